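"""Uncorrected pairwise distances, haplotype collapsing and gap summaries.

p-distance = mismatches / compared sites under pairwise deletion: for each
sequence pair only sites where both rows carry an unambiguous A/C/G/T are
compared.  Pairs with fewer than ``min_overlap`` comparable sites are kept
but flagged; pairs with zero comparable sites get NaN and a flag.  Nothing
here assumes the triangle inequality (p-distances on ambiguity-heavy rows
may violate it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .qc import AlignedMatrix

MIN_OVERLAP = 100

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(rows) -> np.ndarray:
    """Byte-encode rows: A,C,G,T -> 0..3, anything else (gap/ambiguity) -> 4."""
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(rows), -1)


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray
    compared_sites: np.ndarray
    flagged_pairs: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DistanceError("distance matrix shape mismatch")

    def __len__(self):
        return len(self.ids)

    def index(self, i: str) -> int:
        return self.ids.index(i)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = {j: i for i, j in enumerate(self.ids)}
        keep = np.array([idx[i] for i in ids])
        kept = set(ids)
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(keep, keep)].copy(),
            compared_sites=self.compared_sites[np.ix_(keep, keep)].copy(),
            flagged_pairs=[p for p in self.flagged_pairs if p[0] in kept and p[1] in kept],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{name:<12s}{row}\n")


def p_distance(a: str, b: str):
    """p-distance between two equal-length aligned rows.

    Returns ``(distance, compared_sites)``; sites where either row has a
    gap/pad or ambiguity code are excluded.
    """
    if len(a) != len(b):
        raise DistanceError("rows of unequal length")
    ca, cb = encode([a])[0], encode([b])[0]
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n == 0:
        raise DistanceError("no comparable sites between rows")
    mism = int(((ca != cb) & valid).sum())
    return mism / n, n


def distance_matrix(alignment: AlignedMatrix, min_overlap: int = MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs p-distance matrix with pairwise deletion.

    Low-overlap pairs (< ``min_overlap`` comparable sites) are flagged;
    zero-overlap pairs additionally get ``d = NaN``.
    """
    if len(alignment.ids) < 2:
        raise DistanceError("need at least 2 aligned rows")
    return matrix_from_codes(list(alignment.ids), encode(alignment.rows), min_overlap)


def matrix_from_codes(ids, codes: np.ndarray, min_overlap: int = MIN_OVERLAP) -> DistanceMatrix:
    """p-distance matrix from a byte-encoded alignment (codes 0..3 valid, 4 masked)."""
    valid = codes < 4
    n = codes.shape[0]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    flagged = []
    # blocked broadcast keeps memory ~n*L per row
    for i in range(n):
        v = valid[i] & valid[i + 1 :]
        m = ((codes[i] != codes[i + 1 :]) & v).sum(axis=1)
        s = v.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            sites[i, j] = sites[j, i] = s[k]
            if s[k] == 0:
                d[i, j] = d[j, i] = np.nan
                flagged.append((ids[i], ids[j], "zero_overlap"))
            else:
                d[i, j] = d[j, i] = m[k] / s[k]
                if s[k] < min_overlap:
                    flagged.append((ids[i], ids[j], "low_overlap"))
    np.fill_diagonal(sites, 0)
    return DistanceMatrix(ids=list(ids), d=d, compared_sites=sites, flagged_pairs=flagged)


def _zero_components(dm: DistanceMatrix, min_sites: int = MIN_OVERLAP):
    """Transitive closure of the 'identical barcode' relation (single
    linkage at distance exactly 0 over >= min_sites compared sites)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(dm.ids)
    adj = (dm.d == 0) & (dm.compared_sites >= min_sites)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def collapse_haplotypes(dm: DistanceMatrix, group: dict, min_sites: int = MIN_OVERLAP) -> dict:
    """Per-species unique-haplotype counts.

    Two specimens share a haplotype iff their p-distance is exactly 0 over
    at least ``min_sites`` compared sites, closed transitively.
    """
    labels = _zero_components(dm, min_sites)
    per_species = {}
    for sid, comp in zip(dm.ids, labels):
        sp = group[sid]
        per_species.setdefault(sp, set()).add(comp)
    return {sp: len(comps) for sp, comps in per_species.items()}


@dataclass
class SpeciesSummary:
    species_label: str
    n_specimens: int
    n_haplotypes: int
    mean_intra: Optional[float]
    max_intra: Optional[float]
    nn_distance: float
    nn_species: str


def species_summary(dm: DistanceMatrix, specimens, min_sites: int = MIN_OVERLAP) -> list:
    """Intraspecific means/maxima and nearest-neighbour distances.

    ``specimens`` maps ids to metadata (or is a list of SpecimenRecord).
    Genus-only, hybrid, provisional and suspect records are excluded, as in
    barcode-gap plots (misidentifications and unidentifiable labels would
    contaminate both the intra and inter distributions).
    """
    if not isinstance(specimens, dict):
        specimens = {m.specimen_id: m for m in specimens}
    keep_ids = [
        i
        for i in dm.ids
        if i in specimens
        and specimens[i].label_rank == "species"
        and not specimens[i].suspect_misid
    ]
    sub = dm.submatrix(keep_ids)
    labels = np.array([specimens[i].species_label for i in keep_ids])
    haplo = collapse_haplotypes(sub, {i: specimens[i].species_label for i in keep_ids}, min_sites)
    out = []
    for sp in sorted(set(labels)):
        mask = labels == sp
        idx = np.where(mask)[0]
        n_sp = len(idx)
        if n_sp >= 2:
            block = sub.d[np.ix_(idx, idx)]
            vals = block[np.triu_indices(n_sp, k=1)]
            vals = vals[~np.isnan(vals)]
            mean_intra = float(vals.mean()) if vals.size else None
            max_intra = float(vals.max()) if vals.size else None
        else:
            mean_intra = max_intra = None
        other = np.where(~mask)[0]
        if other.size == 0:
            continue
        cross = sub.d[np.ix_(idx, other)]
        with np.errstate(invalid="ignore"):
            j = int(np.nanargmin(cross.min(axis=0)))
        nn_distance = float(np.nanmin(cross))
        nn_species = str(labels[other[j]])
        out.append(
            SpeciesSummary(
                species_label=sp,
                n_specimens=n_sp,
                n_haplotypes=haplo.get(sp, 0),
                mean_intra=mean_intra,
                max_intra=max_intra,
                nn_distance=nn_distance,
                nn_species=nn_species,
            )
        )
    return out


def cluster_summary(dm: DistanceMatrix, assignment: dict):
    """Within-cluster mean distances and between-cluster mean distances.

    Returns ``(internal, between)``: internal maps cluster -> mean
    within-cluster p-distance (None for singletons); between maps each
    unordered cluster pair -> mean distance over all cross pairs.
    """
    missing = [i for i in dm.ids if i not in assignment]
    if missing:
        raise DistanceError(f"assignment missing ids: {missing[:5]}")
    clusters = {}
    for i, sid in enumerate(dm.ids):
        clusters.setdefault(assignment[sid], []).append(i)
    internal = {}
    for c, idx in clusters.items():
        if len(idx) < 2:
            internal[c] = None
        else:
            block = dm.d[np.ix_(idx, idx)]
            vals = block[np.triu_indices(len(idx), k=1)]
            internal[c] = float(np.nanmean(vals))
    between = {}
    names = sorted(clusters, key=str)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            cross = dm.d[np.ix_(clusters[a], clusters[b])]
            between[(a, b)] = float(np.nanmean(cross))
    return internal, between


def barcode_gap_table(summaries) -> pd.DataFrame:
    """Per-species barcode-gap flags: max intraspecific < nearest neighbour."""
    rows = []
    for s in summaries:
        if s.max_intra is None:
            gap = None
        else:
            gap = bool(s.max_intra < s.nn_distance)
        rows.append(
            {
                "species_label": s.species_label,
                "n_specimens": s.n_specimens,
                "n_haplotypes": s.n_haplotypes,
                "mean_intra_pct": None if s.mean_intra is None else round(100 * s.mean_intra, 2),
                "max_intra_pct": None if s.max_intra is None else round(100 * s.max_intra, 2),
                "nn_distance_pct": round(100 * s.nn_distance, 2),
                "nn_species": s.nn_species,
                "barcode_gap": gap,
            }
        )
    return pd.DataFrame(rows)
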