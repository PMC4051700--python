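"""Morphospecies-versus-cluster concordance (MATCH/SPLIT/MERGE/MIXTURE).

Each species-rank label is compared against the clusters (BINs/MOTUs) its
specimens occupy:

* MATCH   — one cluster, occupied only by that species;
* SPLIT   — several clusters, each occupied only by that species;
* MERGE   — one shared cluster whose every co-occupant species occupies
            exactly that same cluster and nothing else;
* MIXTURE — any more complex sharing (co-occupants that also occur
            elsewhere, or co-occupants whose identity is unestablished:
            genus-only, hybrid, provisional or suspected-misidentified
            records).

Curation flags drive the bookkeeping: a specimen flagged as a suspected
misidentification is removed from its labelled species' cluster set but
still occupies its cluster (under a suspect pseudo-label), so it makes the
cluster heterogeneous without dragging its nominal species into the
tally.  Genus-only, hybrid and provisional records likewise occupy
clusters but are never themselves classified and can never be MERGE
partners.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("MATCH", "SPLIT", "MERGE", "MIXTURE")

_SUSPECT = "__suspect__"


class ConcordanceError(ValueError):
    pass


@dataclass
class ConcordanceResult:
    species_label: str
    category: str
    bins_occupied: list
    heterogeneous_bins: list
    co_occupant_labels: list
    excluded_specimens: list = field(default_factory=list)
    provisional: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConcordanceError(f"unknown category {self.category!r}")


def classify_species(specimens) -> list:
    """Classify every species-rank (and provisional) label against its bins.

    Every record must carry a bin_id.  Records of rank genus_only/hybrid
    and suspect-flagged records are not classified but do count as bin
    occupants.
    """
    missing = [m.specimen_id for m in specimens if not m.bin_id]
    if missing:
        raise ConcordanceError(f"records missing bin_id: {missing[:10]}")

    occupants = {}  # bin -> Counter of effective labels
    bins_of = {}  # classifiable label -> set of bins (suspects excluded)
    rank_of = {}
    excluded = {}  # label -> [(specimen_id, reason)]
    for m in specimens:
        if m.suspect_misid:
            eff = f"{_SUSPECT}:{m.species_label}"
            excluded.setdefault(m.species_label, []).append(
                (m.specimen_id, "suspected misidentification")
            )
        else:
            eff = m.species_label
        occupants.setdefault(m.bin_id, Counter())[eff] += 1
        if m.suspect_misid:
            continue
        if m.label_rank in ("species", "provisional"):
            bins_of.setdefault(m.species_label, set()).add(m.bin_id)
            rank_of[m.species_label] = m.label_rank

    results = []
    for label in sorted(bins_of):
        B = sorted(bins_of[label])
        hetero = [
            b for b in B if any(eff != label for eff in occupants[b])
        ]
        co = sorted(
            {
                eff
                for b in B
                for eff in occupants[b]
                if eff != label
            }
        )
        if not hetero:
            category = "MATCH" if len(B) == 1 else "SPLIT"
        elif len(B) == 1:
            # MERGE requires every co-occupant to be an established species
            # occupying exactly the same single bin
            partners_ok = all(
                not c.startswith(_SUSPECT)
                and rank_of.get(c) == "species"
                and bins_of.get(c) == bins_of[label]
                for c in co
            )
            category = "MERGE" if partners_ok else "MIXTURE"
        else:
            category = "MIXTURE"
        results.append(
            ConcordanceResult(
                species_label=label,
                category=category,
                bins_occupied=B,
                heterogeneous_bins=hetero,
                co_occupant_labels=co,
                excluded_specimens=excluded.get(label, []),
                provisional=rank_of[label] == "provisional",
            )
        )
    return results


def category_counts(results) -> dict:
    """Category tallies over species-rank results (provisional labels such
    as open-nomenclature 'cf.' rows are listed but not counted)."""
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        if not r.provisional:
            counts[r.category] += 1
    return counts


def specimens_vs_haplotypes(summaries, results) -> pd.DataFrame:
    """Sampling-effort table: specimens vs unique haplotypes per species.

    The outlier flag marks species with high sampling effort *and* many
    distinct haplotypes (>= 5 of each) — the pattern expected when a
    nominal species hides divergent lineages rather than shallow noise.
    """
    cat = {r.species_label: r.category for r in results}
    rows = [
        {
            "species_label": s.species_label,
            "n_specimens": s.n_specimens,
            "n_haplotypes": s.n_haplotypes,
            "category": cat.get(s.species_label, ""),
            "outlier": bool(s.n_specimens >= 5 and s.n_haplotypes >= 5),
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("n_specimens", ascending=False, kind="stable").reset_index(drop=True)
    return df
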