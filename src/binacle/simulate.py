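"""Synthetic COI barcode datasets with known species truth.

The generator emulates the structure of a single-family barcode
calibration study: a modest number of species, 1–35 specimens each,
~650 bp ORF-clean fragments of a protein-coding mitochondrial gene, tight
within-species variation (a fraction of a percent), species separated by
several percent, some species split into divergent geographic haplogroups,
and optional pseudogene (NUMT-like) contamination as a QC negative
control.

Sequences descend from a packaged synthetic 652-nt open reading frame
(composition tuned near T 28 / C 30 / G 18 / A 24, vertebrate
mitochondrial code; not a database sequence).  Species ancestors evolve
along a simulated pure-birth tree; substitutions fall 70% on third codon
positions and any substitution creating a stop codon is redrawn, so every
non-pseudogene record stays ORF-clean.  Records are randomly truncated to
561..L nt with the true template offset recorded, which exercises the
translation-guided aligner end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from dendropy.simulate import treesim

from .io import SequenceRecord, SpecimenRecord
from .qc import translate_mito

#: vertebrate mitochondrial stop codons
_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_BASES = "ACGT"
#: target base composition (T, C, G, A) for the packaged template
_TEMPLATE_PROBS = {"T": 0.28, "C": 0.30, "G": 0.18, "A": 0.24}
_TEMPLATE_SEED = 712

MIN_FRAGMENT = 561
THIRD_POSITION_BIAS = 0.7


class SimulationError(ValueError):
    pass


@lru_cache(maxsize=8)
def coi_template(length: int = 652) -> str:
    """Deterministic ORF-clean template of ``length`` nt (frame 0).

    Fixed internal seed: the template is part of the package, not of any
    particular simulation.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    bases = list(_TEMPLATE_PROBS)
    probs = list(_TEMPLATE_PROBS.values())
    n_codons = (length + 2) // 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases, size=3, p=probs))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)[:length]


def default_profile(length: int = 652) -> str:
    """Amino-acid profile of the packaged template (user-replaceable)."""
    return translate_mito(coi_template(length), 0)


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 25
    specimens_per_species: tuple = (1, 35)
    seq_length: int = 652
    intraspecific_theta: float = 0.003
    interspecific_range: tuple = (0.04, 0.10)
    split_species: tuple = ()  # ((species_index, haplogroup_divergence), ...)
    pseudogene_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.interspecific_range
        if not lo <= hi:
            raise SimulationError("interspecific_range must be (min, max)")
        if lo <= self.intraspecific_theta:
            raise SimulationError("interspecific min must exceed intraspecific theta")
        for r in (self.intraspecific_theta, self.pseudogene_rate, lo, hi):
            if not 0 <= r <= 1:
                raise SimulationError(f"rate {r} outside [0, 1]")
        if hi > 0.35:
            # stop-rejected mutation cannot realize such divergence reliably
            raise SimulationError("interspecific max too large for ORF-preserving simulation")
        if self.n_species < 1 or self.specimens_per_species[0] < 1:
            raise SimulationError("need >= 1 species and >= 1 specimen per species")


@dataclass
class SimTruth:
    species_of: dict  # specimen id -> species label
    haplogroup_of: dict  # specimen id -> haplogroup ("A"/"B")
    is_pseudogene: dict  # specimen id -> bool
    offsets: dict  # specimen id -> true template offset (nt)
    tree: object = None  # species tree (dendropy)


def _mutate(seq: str, n_sub: int, rng) -> str:
    """Apply ``n_sub`` substitutions, 70% at third codon positions, never
    creating a frame-0 stop codon."""
    s = list(seq)
    n_codons = len(s) // 3
    for _ in range(n_sub):
        for _try in range(100):
            if rng.random() < THIRD_POSITION_BIAS:
                pos = 3 * rng.integers(n_codons) + 2
            else:
                codon = rng.integers(n_codons)
                pos = 3 * codon + rng.integers(2)
            old = s[pos]
            new = _BASES[rng.integers(4)]
            if new == old:
                continue
            c0 = 3 * (pos // 3)
            codon_seq = s[c0 : c0 + 3]
            codon_seq[pos - c0] = new
            if "".join(codon_seq) in _STOPS:
                continue
            s[pos] = new
            break
        else:
            raise SimulationError("could not place a stop-free substitution")
    return "".join(s)


def _species_ancestors(config: SimConfig, rng) -> tuple:
    """Evolve species ancestors along a pure-birth tree.

    The tree is scaled so the deepest tip pair diverges by the interspecific
    maximum, and terminal branches are stretched to guarantee every pair
    diverges by at least the interspecific minimum.
    """
    template = coi_template(config.seq_length)
    lo, hi = config.interspecific_range
    if config.n_species == 1:
        return [template], None
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=random.Random(int(rng.integers(2**31))),
    )
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    scale = (hi / 2) / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = max(leaf.edge.length or 0.0, lo / 2)

    L = len(template)
    seqs = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = template
        else:
            n_sub = int(rng.binomial(L, min(node.edge.length, 1.0)))
            seqs[node] = _mutate(seqs[node.parent_node], n_sub, rng)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    ancestors = [seqs[l] for l in leaves]

    # binomial draws and homoplasy can leave a sister pair short of the
    # interspecific minimum; top up the later lineage until every ancestor
    # pair realizes at least `lo` divergence
    def _pdist(a, b):
        return sum(x != y for x, y in zip(a, b)) / L

    floor = int(np.ceil(lo * L))
    for _ in range(50 * config.n_species):
        worst = min(
            ((i, j) for i in range(len(ancestors)) for j in range(i + 1, len(ancestors))),
            key=lambda p: _pdist(ancestors[p[0]], ancestors[p[1]]),
        )
        if _pdist(ancestors[worst[0]], ancestors[worst[1]]) * L >= floor:
            break
        ancestors[worst[1]] = _mutate(ancestors[worst[1]], max(2, floor // 20), rng)
    else:
        raise SimulationError("could not realize the interspecific minimum")
    return ancestors, tree


def simulate(config: SimConfig):
    """Generate ``(sequence records, specimen metadata, SimTruth)``.

    Deterministic under ``config.seed``: same config, byte-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    ancestors, tree = _species_ancestors(config, rng)
    split = dict(config.split_species)
    hap_ancestors = {}
    for si, anc in enumerate(ancestors):
        hap_ancestors[(si, "A")] = anc
        if si in split:
            n_sub = int(round(split[si] * L))
            hap_ancestors[(si, "B")] = _mutate(anc, n_sub, rng)

    lo_n, hi_n = config.specimens_per_species
    records, specimens = [], []
    truth = SimTruth(species_of={}, haplogroup_of={}, is_pseudogene={}, offsets={}, tree=tree)
    for si in range(config.n_species):
        species = f"Species_{si:02d}"
        n = int(rng.integers(lo_n, hi_n + 1))
        for k in range(n):
            hap = "B" if (si in split and k % 2 == 1) else "A"
            anc = hap_ancestors[(si, hap)]
            n_sub = int(rng.binomial(L, config.intraspecific_theta / 2))
            seq = _mutate(anc, n_sub, rng)
            lo_len = min(MIN_FRAGMENT, L)
            length = int(rng.integers(lo_len, L + 1))
            start = int(rng.integers(0, L - length + 1))
            frag = seq[start : start + length]
            sid = f"SIM{si:02d}-{k:03d}"
            is_pg = bool(rng.random() < config.pseudogene_rate)
            rec = SequenceRecord(id=sid, seq=frag)
            if is_pg:
                rec = inject_pseudogene(rec, seed=int(rng.integers(2**31)))
            records.append(rec)
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species_label=species,
                    label_rank="species",
                    is_reference=True,
                    country=f"Country_{si:02d}{hap}",
                )
            )
            truth.species_of[sid] = species
            truth.haplogroup_of[sid] = hap
            truth.is_pseudogene[sid] = is_pg
            truth.offsets[sid] = start
    return records, specimens, truth


def inject_pseudogene(record: SequenceRecord, seed: int) -> SequenceRecord:
    """Turn an ORF-clean record into a NUMT-like QC negative control.

    With equal probability, either an internal codon becomes a stop codon,
    or one nucleotide is deleted.  The deletion lands away from both
    sequence ends: an ungapped register check needs enough clean sequence
    on each side of the shift to anchor the two registers independently.
    """
    from .qc import detect_reading_frame

    rng = np.random.default_rng(seed)
    s = record.seq
    if rng.random() < 0.5:
        frame, _ = detect_reading_frame(s)
        f = frame if frame is not None else 0
        n_codons = (len(s) - f) // 3
        c = f + 3 * int(rng.integers(1, n_codons - 1))
        s = s[:c] + "TAA" + s[c + 3 :]
    else:
        lo, hi = 160, len(s) - 170
        if hi <= lo:
            lo, hi = len(s) // 3, 2 * len(s) // 3
        p = int(rng.integers(lo, hi))
        s = s[:p] + s[p + 1 :]
    return SequenceRecord(id=record.id, seq=s, source=record.source)


def score_partition(truth: SimTruth, partition) -> tuple:
    """Score a partition against simulated species truth.

    Returns ``(adjusted Rand index, split_errors, merge_errors)`` where
    split errors are true species spanning several clusters beyond any
    configured haplogroup split, and merge errors are clusters spanning
    several true species.
    """
    from sklearn.metrics import adjusted_rand_score

    assignment = partition.assignment if hasattr(partition, "assignment") else partition
    ids = sorted(truth.species_of)
    if set(ids) != set(assignment):
        raise SimulationError("partition and truth cover different specimens")
    y_true = [truth.species_of[i] for i in ids]
    y_pred = [assignment[i] for i in ids]
    ari = float(adjusted_rand_score(y_true, y_pred))

    clusters_of = {}
    for i in ids:
        clusters_of.setdefault(truth.species_of[i], set()).add(assignment[i])
    split_hap = {  # species simulated with two haplogroups may occupy two clusters
        sp
        for sp in clusters_of
        if len({truth.haplogroup_of[i] for i in ids if truth.species_of[i] == sp}) > 1
    }
    split_errors = [
        sp
        for sp, cl in clusters_of.items()
        if len(cl) > (2 if sp in split_hap else 1)
    ]
    species_of_cluster = {}
    for i in ids:
        species_of_cluster.setdefault(assignment[i], set()).add(truth.species_of[i])
    merge_errors = [c for c, sps in species_of_cluster.items() if len(sps) > 1]
    return ari, sorted(split_errors), sorted(merge_errors)
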