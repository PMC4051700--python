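"""Cluster-membership identification of query (non-native/market) specimens.

A query is identified by re-clustering it together with the reference
library and reading off shared cluster membership — not by nearest-
neighbour thresholding.  An identification is successful when the query
lands in a cluster that contains expert-identified reference specimens and
whose species' concordance category (computed on the references alone,
before query insertion) is MATCH or SPLIT; a MIXTURE cluster leaves the
identity ambiguous at the species-pair level.  Queries that land in
clusters with no reference members are flagged as new clusters.  The
nearest-reference distance is always reported for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import qc as _qc
from .cluster import BinRegistry, resl_partition
from .concordance import classify_species
from .distances import distance_matrix
from .io import ReferenceLibrary, SpecimenRecord


class IdentifyError(ValueError):
    pass


@dataclass
class IdentificationResult:
    query_id: str
    assigned_cluster: Optional[str]
    co_member_species: list
    success: bool
    nearest_reference_id: Optional[str]
    nearest_reference_distance: Optional[float]
    is_new_cluster: bool
    cluster_category: str = ""
    co_member_ids: list = field(default_factory=list)
    note: str = ""


def _merge_alignments(a: _qc.AlignedMatrix, b: _qc.AlignedMatrix) -> _qc.AlignedMatrix:
    """Concatenate two matrices sharing the same profile coordinate system."""
    width = max(a.columns, b.columns)
    rows = [r + "-" * (width - len(r)) for r in a.rows] + [
        r + "-" * (width - len(r)) for r in b.rows
    ]
    return _qc.AlignedMatrix(ids=list(a.ids) + list(b.ids), rows=rows, offsets=list(a.offsets) + list(b.offsets))


def identify_queries(
    library: ReferenceLibrary,
    queries,
    profile: str,
    seed_threshold: float = None,
    registry: BinRegistry = None,
    **resl_kwargs,
) -> list:
    """Assign each query sequence to a MOTU of the combined clustering.

    ``library.alignment`` must already be computed (same amino-acid
    profile).  Queries failing QC are reported unidentifiable, never
    silently dropped.
    """
    if library.alignment is None:
        raise IdentifyError("library has no alignment; run QC/alignment first")
    if seed_threshold is not None:
        resl_kwargs["seed_threshold"] = seed_threshold

    meta = library.specimen_map()
    ref_ids = list(library.alignment.ids)

    q_matrix, q_reports = _qc.align_records(queries, profile)
    failed = {r.specimen_id: r for r in q_reports if not r.passed}

    results = []
    for qid, rep in failed.items():
        reason = "stop codons" if rep.stop_codons else "indel vs profile"
        results.append(
            IdentificationResult(
                query_id=qid,
                assigned_cluster=None,
                co_member_species=[],
                success=False,
                nearest_reference_id=None,
                nearest_reference_distance=None,
                is_new_cluster=False,
                note=f"unidentifiable: failed QC ({reason})",
            )
        )
    if not q_matrix.ids:
        return results

    combined = _merge_alignments(library.alignment, q_matrix)
    dm_all = distance_matrix(combined)

    # reference-only categories, computed before query insertion
    dm_ref = dm_all.submatrix(ref_ids)
    ref_partition = resl_partition(dm_ref, registry=BinRegistry(), **resl_kwargs)
    ref_specimens = [
        SpecimenRecord(
            specimen_id=m.specimen_id,
            species_label=m.species_label,
            label_rank=m.label_rank,
            is_reference=m.is_reference,
            suspect_misid=m.suspect_misid,
            country=m.country,
            bin_id=ref_partition.assignment[m.specimen_id],
        )
        for m in library.specimens
        if m.specimen_id in ref_partition.assignment
    ]
    category_of = {r.species_label: r.category for r in classify_species(ref_specimens)}

    joint = resl_partition(dm_all, registry=registry or BinRegistry(), **resl_kwargs)
    clusters = joint.clusters()
    by_member = {sid: lab for lab, members in clusters.items() for sid in members}

    reference_ids = [i for i in ref_ids if meta[i].is_reference]
    for qid in q_matrix.ids:
        lab = by_member[qid]
        members = clusters[lab]
        co_ref = [m for m in members if m in meta and meta[m].is_reference]
        co_species = sorted(
            {
                meta[m].species_label
                for m in co_ref
                if meta[m].label_rank == "species" and not meta[m].suspect_misid
            }
        )
        ambiguous_co = any(
            meta[m].label_rank != "species" or meta[m].suspect_misid for m in co_ref
        )
        if not co_ref:
            cluster_category = ""
        elif len(co_species) == 1 and not ambiguous_co:
            cluster_category = category_of.get(co_species[0], "MIXTURE")
        else:
            cluster_category = "MIXTURE"
        if reference_ids:
            dists = [dm_all.get(qid, r) for r in reference_ids]
            k = int(np.nanargmin(dists))
            nearest_id, nearest_d = reference_ids[k], float(dists[k])
        else:
            nearest_id, nearest_d = None, None
        is_new = len(co_ref) == 0
        success = (not is_new) and cluster_category in ("MATCH", "SPLIT")
        note = ""
        if cluster_category == "MIXTURE" and co_species:
            note = "species-pair resolution only: " + " / ".join(co_species)
        elif is_new:
            note = "no reference specimens in cluster (new cluster)"
        results.append(
            IdentificationResult(
                query_id=qid,
                assigned_cluster=lab,
                co_member_species=co_species,
                success=success,
                nearest_reference_id=nearest_id,
                nearest_reference_distance=nearest_d,
                is_new_cluster=is_new,
                cluster_category=cluster_category,
                co_member_ids=sorted(co_ref),
                note=note,
            )
        )
    return results


def provenance_report(results, specimens) -> pd.DataFrame:
    """Countries of the reference specimens co-clustered with each query.

    Phylogeographically structured clusters make these country sets
    informative about the likely origin of an introduced specimen; queries
    in new clusters get an empty provenance.
    """
    if not isinstance(specimens, dict):
        specimens = {m.specimen_id: m for m in specimens}
    rows = []
    for r in results:
        countries = sorted(
            {
                specimens[m].country
                for m in r.co_member_ids
                if m in specimens and specimens[m].country
            }
        )
        rows.append(
            {
                "query_id": r.query_id,
                "assigned_cluster": r.assigned_cluster or "",
                "success": r.success,
                "provenance": "; ".join(countries),
            }
        )
    return pd.DataFrame(rows)
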