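# Methods

## Scope and model

The package treats a DNA-barcode study as a fixed sequence of decisions:
which sequences are trustworthy (QC), how far apart they are (p-distances),
how they cluster into species-like units (MOTUs), how those units relate to
the names specimens carry (concordance), and what that implies for unknown
specimens (identification). Each stage is a pure function of its inputs
plus explicitly recorded parameters and seeds.

### Sequence QC and alignment

COI barcodes from vertebrates are expected to be indel-free open reading
frames under the mitochondrial code (translation table 2, configurable).
Two pseudogene (NUMT) signatures are screened:

- **Stop codons.** Each sequence is translated in all three frames; the
  reading frame is the smallest frame index with zero stops, and a sequence
  with stops in every frame has no frame (`frame = none`). Frames of
  truncated fragments are relative to the fragment, so a fragment starting
  mid-codon legitimately has frame 1 or 2.
- **Frameshifts.** Whole-sequence amino-acid identity against a reference
  profile is necessary but not sufficient: an ungapped aligner re-anchors on
  the longer clean side of an indel and can report high identity for a
  frameshifted sequence. Sequences are therefore also cut into ~150-nt
  chunks, each placed independently against the profile (frame chosen by
  identity, since 50-codon windows can be stop-free in a wrong frame by
  chance); in an indel-free sequence the recovered profile coordinates
  advance exactly with the cut positions, and any offset jump marks a
  frameshift. A record fails QC iff it has stop codons or a frameshift
  (equivalently, whole-sequence identity below 0.5 also sets the indel
  flag). Candidate placements must overlap the profile by >= 20 residues so
  short perfect overlaps cannot outscore long good ones.

Alignment is the byproduct of QC: the best profile placement fixes each
sequence's nucleotide offset, and rows are padded with `-` into an
equal-length matrix. There is no gapped alignment by design — in this data
model an indel is evidence of a pseudogene, not something to rescue.

The packaged profile is the translation of a synthetic 652-nt ORF-clean
template (fixed internal seed, composition tuned near T 28% / C 30% /
G 18% / A 24%); it is user-replaceable by any COI amino-acid profile.

### Distances

p-distance = mismatches / compared sites under pairwise deletion: per pair,
sites where either row has a gap, pad or ambiguity code are excluded.
Pairwise deletion maximizes usable sites across fragments of unequal length
(561–666 nt); pairs with fewer than 100 comparable sites are flagged rather
than trusted, and zero-overlap pairs get NaN. No model correction (K2P
etc.) is applied anywhere. Nothing downstream assumes the triangle
inequality, which p-distances on ambiguity-heavy rows can violate.

Haplotypes are equivalence classes of the relation "p-distance exactly 0
over >= 100 compared sites", closed transitively (single linkage at
distance zero); this makes haplotype counts well defined when fragments
overlap partially. Base composition is pooled over all unambiguous bases of
all sequences (with near-equal sequence lengths this is indistinguishable
from the mean of per-sequence frequencies).

Species summaries exclude genus-only, hybrid, provisional ("cf.") and
suspected-misidentified records: such records would contaminate both the
intraspecific and the nearest-neighbour distributions that the barcode-gap
flag (`max intra < nearest neighbour`) compares.

### Neighbour joining and bootstrap

Saitou–Nei neighbour joining with the Studier–Keppler O(n^3) criterion
Q(i,j) = (n−2) d(i,j) − r(i) − r(j). Determinism is part of the contract:
taxa are processed in sorted-id order regardless of caller row order (float
summation order in r would otherwise make near-ties order-dependent), the
row sums are grouped as (r_i + r_j) so Q is exactly symmetric in floating
point, and Q-ties break toward the lexicographically smallest pair of
subtree keys (a subtree's key is its smallest leaf id). Negative branch
estimates are clamped to zero for display with the raw value kept as an
edge annotation. On additive matrices the tree's path metric reproduces the
input to < 1e-9 (tested against randomly generated additive matrices).

Bootstrap: alignment columns are resampled with replacement; replicate r
uses an independent RNG stream keyed by (seed, r), so supports are
reproducible and replicates are order-independent. Support of an internal
edge is the percentage of replicate trees containing its (canonicalized,
unrooted) bipartition; replicates that produce a zero-overlap pair are
skipped. Distances inside replicates use pairwise deletion on the resampled
columns, consistent with the main distance stage.

### MOTU partitioning (refined single linkage)

1. **Seeds**: connected components of the graph with edges d <= 2.2%
   (the published seed threshold for refined single linkage; configurable).
2. **Candidates** per seed cluster: the unsplit cluster; single-linkage
   cuts over a 0.5%–3.0% grid (step 0.1%); Markov clustering of the
   similarity matrix s_ij = max(0, 1 − d_ij / t0) (unit self-loops, column
   normalization, expansion = matrix square, inflation = elementwise power
   at 1.5 / 2.0 / 3.0, tolerance 1e-6, <= 200 iterations, non-convergence
   returns the current state with a warning).
3. **Selection**: mean silhouette on the seed-cluster submatrix, with
   s(i) = 0 for singleton-cluster members and 0 by convention for
   one-cluster partitions; ties break toward fewer clusters, then the
   lexicographically smallest canonical assignment. A refinement is
   accepted only if (a) its silhouette is >= 0.5 and (b) its clusters are
   separated by at least 1% p-distance (`min_split_gap`). Condition (b) is
   this package's addition: silhouette alone scores ~0.75 for a spurious
   cut of a homogeneous cloud whose members happen to be nearly identical,
   and real barcode data keep species with up to ~1% internal variation in
   a single cluster. Both thresholds are configurable.
4. **Labels**: a content-addressed registry maps each cluster's member set
   to a stable AAA0001-style label; re-clustering identical data reproduces
   identical labels, and adding a divergent specimen mints a new label
   without relabelling old clusters. Official BIN identifiers cannot be
   reproduced by construction; analyses that need them accept bin ids from
   specimen metadata instead (`bin_source="metadata"`), which is also how
   published concordance counts are verified independently of this
   clustering.

Refinement only ever subdivides seed clusters; it never merges them.

### Concordance

For species S with cluster set B(S) (suspect records excluded from B(S) but
still occupying their cluster under a suspect pseudo-label):

- every cluster in B(S) pure → MATCH if |B(S)| = 1 else SPLIT;
- |B(S)| = 1, the cluster shared, and every co-occupant an established
  species occupying exactly that cluster → MERGE;
- anything else → MIXTURE.

Genus-only, hybrid and provisional occupants make a cluster heterogeneous
but can never be MERGE partners — their identity is unestablished, so the
outcome is MIXTURE. Provisional labels ("C. cf. ...") are classified for
reporting but excluded from category tallies. Suspect flags are curation
inputs, never inferences; the packaged fixture ships the curation under
which the published tallies (14 MATCH / 9 SPLIT / 2 MIXTURE / 0 MERGE over
25 species) are reproducible, and users can edit them.

### Identification

Queries are re-clustered together with the reference library (shared
cluster membership, not nearest-neighbour thresholding). Success requires
co-clustering with >= 1 expert-identified reference whose species'
reference-only category (computed before query insertion, so adding queries
never changes the library's reported categories) is MATCH or SPLIT.
MIXTURE co-membership yields a species-pair note instead of a success;
reference-free clusters are flagged new. Nearest-reference distance and the
countries of co-clustered references are always reported — with
phylogeographically structured clusters the country set is informative
about the likely origin of an introduced specimen. Identification is
maternal-lineage only; hybrids with a reference maternal parent are
indistinguishable from that parent by design.

## Synthetic data generator

The generator emulates the structure of a single-family barcode
calibration: n_species (default 25) with 1–35 specimens each, 652-nt
ORF-clean template fragments truncated to 561–652 nt at random offsets,
intraspecific divergence ~0.3% (theta default 0.003; specimens mutate at
theta/2 from their ancestor so mean pairwise intra ≈ theta), interspecific
divergences 4–10%, optional haplogroup splits at a stated divergence, and
optional pseudogene contamination.

Mechanics and their justifications:

- Species ancestors evolve along a simulated pure-birth tree scaled so the
  deepest pair diverges by the interspecific maximum; terminal branches are
  floored at half the minimum. Because binomial substitution draws and
  homoplasy undershoot nominal divergence, ancestor pairs are topped up
  until every pair realizes the interspecific minimum — the configured
  range is a guarantee, not a hint.
- Substitutions fall 70% on third codon positions and any substitution that
  would create a stop codon (in the template frame) is redrawn, so clean
  output always passes QC.
- Pseudogene injection flips a fair coin between an in-frame stop codon
  (placed on the fragment's own reading frame) and a 1-nt deletion. The
  deletion is placed >= 160 nt from both ends: an ungapped register check
  cannot detect a frameshift without enough clean sequence on each side to
  anchor both registers, and a deletion within the terminal codons of a
  fragment is genuinely invisible to any gap-free method.

What the generator does **not** emulate: coalescent population structure,
migration, rate variation among lineages, indel evolution, sequencing
error, or ambiguity codes. Passing the synthetic benchmarks therefore
demonstrates algorithmic correctness under clean barcode-like structure —
it does not certify performance on low-quality or recently diverged real
data, where barcode gaps may be absent.

## Benchmark conditions and problem sizes

The test suite runs entirely on synthetic data at deliberately modest sizes
(8–10 species, 3–8 specimens each, ~40–60 sequences per dataset; 20
datasets for the recovery benchmark; 100 random 8-taxon matrices for the
neighbour-joining oracle; 50 planted matrices for Markov clustering; 500
bootstrap replicates is the production default but tests use 10–100). The
clustering recovery benchmark generates its datasets at theta = 0.0015 and
interspecific range (0.06, 0.12) so that every dataset realizes a barcode
gap ratio (min inter / max intra) of at least 5, the regime in which
gap-based partitioning is expected to be essentially exact; under the
study-like defaults (theta 0.003, inter 0.04–0.10) realized ratios of
2.5–5 still give adjusted Rand indices >= 0.95 but are not guaranteed to.

## Numerical choices

- Percent values in reports are rounded to 2 decimals.
- Distance computations are exact integer ratios (mismatches/sites).
- MCL: tolerance 1e-6 on the max entry change, <= 200 iterations,
  attractors read from rows with positive diagonal mass (> 1e-9);
  overlapping attractor systems resolve to the first attractor in index
  order (deterministic).
- Silhouette uses the p-distance matrix directly (no re-embedding), and is
  computed per seed cluster during refinement — a global b(i) would couple
  unrelated clusters.
- Registry labels: base-26 letter block plus 4 digits, counter starts at
  AAA0001; content hash is SHA-1 of the sorted member ids.
- Degenerate inputs: empty FASTA, missing metadata columns, duplicate ids,
  zero-overlap pairs, sub-60-nt sequences, infeasible simulation configs
  and missing bin ids are all hard errors with the offending names in the
  message; low-overlap pairs and MCL non-convergence are warnings carried
  in the result objects.

## Known limitations

- The MOTU partitioner is a faithful re-implementation of the refined
  single-linkage idea, not a byte-exact clone of the production BIN
  pipeline; cluster boundaries can differ on borderline (1–2.2%) structure.
- Ungapped QC cannot see frameshifts within ~150 nt of a fragment end.
- Identification resolves to species-pair level at best when clusters are
  shared (MIXTURE), and never detects hybrids directly.
- With very small clusters (2–4 members) silhouette is a coarse statistic;
  the min-gap condition carries most of the split/no-split decision there.
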