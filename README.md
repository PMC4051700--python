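# binacle

Calibrating species diversity with COI DNA barcodes: a reusable,
tested pipeline for building a barcode reference library from voucher
specimens, partitioning it into molecular operational taxonomic units
(MOTUs, labelled BIN-style), classifying how morphospecies map onto those
clusters, and identifying unknown or non-native specimens by shared cluster
membership.

The package is aimed at groups like snakehead fishes (Channidae): taxa with
incomplete morphological keys, suspected cryptic diversity, and invasive
potential, where a curated COI library plus cluster-based identification is
the practical route to reliable species assignment at any life stage.

## What it computes

- **Sequence QC** under the vertebrate mitochondrial code: reading-frame
  detection, stop-codon screening, and frameshift detection against a
  reference amino-acid profile (the classic NUMT/pseudogene signatures),
  plus base-composition summaries. Alignment is translation-guided and
  ungapped: the barcode region is expected indel-free, and any indel is a QC
  failure, not an alignment problem.
- **Uncorrected p-distances** with pairwise deletion (per pair, only sites
  where both sequences carry an unambiguous A/C/G/T are compared):
  d = mismatches / compared sites. Per-species summaries report mean and
  maximum intraspecific distance and the nearest-neighbour distance
  min d(x, y) over heterospecific pairs — the two sides of the *barcode
  gap*. Haplotypes are zero-distance equivalence classes (transitively
  closed over >= 100 compared sites).
- **Neighbour-joining phenograms** (Saitou–Nei with the Studier–Keppler
  O(n^3) update) with nonparametric bootstrap supports from column
  resampling; exact on additive matrices, deterministic under ties, Newick
  output with supports as internal node labels.
- **Refined single-linkage MOTU partitioning**: single-linkage seed
  clusters at a 2.2% threshold, candidate refinements per seed cluster
  (finer single-linkage cuts and Markov clustering at several inflations)
  scored by the mean silhouette index
  s(i) = (b(i) − a(i)) / max(a(i), b(i)); a refinement is accepted only if
  it scores >= 0.5 *and* separates its clusters by >= 1% p-distance.
  Clusters receive stable alphanumeric labels (AAA0001, ...) from a
  content-addressed registry.
- **Concordance classification** of each species label against its
  clusters: MATCH (one pure cluster), SPLIT (several pure clusters), MERGE
  (one shared exclusive cluster), MIXTURE (anything more complex, including
  clusters contaminated by genus-only, hybrid or suspected-misidentified
  records).
- **Query identification**: re-cluster queries together with the reference
  library; an identification succeeds when the query lands in a MATCH or
  SPLIT cluster containing expert-identified reference specimens. Queries
  in reference-free clusters are flagged as new clusters; nearest-reference
  distances and the countries of co-clustered references (provenance) are
  always reported.
- **Synthetic COI generator** with known truth — species ancestors evolved
  along a pure-birth tree, ORF-preserving substitutions with third-position
  bias, divergent haplogroup splits, random fragment truncation, optional
  pseudogene injection — so every stage above is testable without any
  download.

## Worked example

Simulate a 6-species reference library and run the whole pipeline:

```
$ binacle simulate --n-species 6 --seed 42 --out-fasta ref.fasta \
      --out-meta ref.tsv --out-truth truth.json
123 records for 6 species
$ binacle run --fasta ref.fasta --meta ref.tsv --outdir out --reps 100 --seed 1
7 stages completed -> out
```

`out/species_report.tsv` now holds one row per (species, cluster) with the
concordance category and divergences in percent:

```
species_label  category  bin          within_bin_pct  within_species_pct  countries
Species_00     MATCH     AAA0001(11)  0.33            0.33                Country_00A
Species_01     MATCH     AAA0002(29)  0.38            0.38                Country_01A
Species_02     MATCH     AAA0003(34)  0.32            0.32                Country_02A
```

All six species come out MATCH: each forms one cluster occupied only by
itself, with ~0.3% mean internal divergence — the intraspecific noise level
the generator was asked for. `out/barcode_gap.tsv` shows why the clustering
is easy here:

```
species_label  n_specimens  n_haplotypes  mean_intra_pct  max_intra_pct  nn_distance_pct  nn_species  barcode_gap
Species_00     11           7             0.33            0.69           4.01             Species_02  True
Species_01     29           22            0.38            1.14           5.87             Species_00  True
```

Every species' largest intraspecific distance (<= 1.4%) sits well below its
nearest-neighbour distance (>= 4%): a clean barcode gap, flagged `True`.
`out/manifest.json` records every stage, parameter, seed and output
checksum; re-running the same config reproduces identical checksums.

The packaged incidence fixture (a published snakehead species-by-BIN
table, with its curation flags) can be classified directly:

```
$ binacle concord --fixture --out fixture.tsv
{"MATCH": 14, "SPLIT": 9, "MERGE": 0, "MIXTURE": 2}
```

14 species map 1:1 onto a single pure cluster, 9 split across several pure
clusters (candidate cryptic diversity), and 2 sit in clusters shared with
other labels (misidentification/hybridization signals).

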