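"""End-to-end barcode calibration pipeline and summary reports.

Stages run in dependency order: import -> qc/align -> distances -> tree ->
cluster -> concordance -> (optional) identification -> report.  Every run
writes a manifest recording parameters, seeds, per-stage row counts and a
checksum for each output file, so a re-run with the same config is
verifiably identical.

``bin_source`` selects where BIN ids come from: ``computed`` uses the
package's refined-single-linkage partition; ``metadata`` trusts bin ids
shipped in the specimen table, which is how published concordance counts
are checked independently of any clustering implementation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import qc as bqc
from .cluster import BinRegistry, resl_partition
from .concordance import category_counts, classify_species, specimens_vs_haplotypes
from .distances import (
    barcode_gap_table,
    cluster_summary,
    collapse_haplotypes,
    distance_matrix,
    species_summary,
)
from .identify import identify_queries, provenance_report
from .io import SpecimenRecord
from .njtree import bootstrap_supports, neighbor_joining
from .simulate import default_profile


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    fasta: str
    meta: str
    outdir: str
    queries_fasta: str = ""
    bin_source: str = "computed"  # computed | metadata
    seed_threshold: float = 0.022
    bootstrap_reps: int = 500
    seed: int = 0
    profile_length: int = 652
    run_tree: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": [], "outputs": {}}

    def stage(name, **info):
        manifest["stages"].append({"name": name, **info})

    def emit(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _checksum(Path(path))}

    for p in (config.fasta, config.meta):
        if not Path(p).exists():
            raise PipelineError(f"missing input path: {p}")

    # import
    seqs = bio.read_fasta(config.fasta)
    specimens = bio.read_specimen_table(config.meta)
    library, join_report = bio.build_library(seqs, specimens)
    (out / "join_report.json").write_text(json.dumps(join_report, indent=1))
    emit("join_report", out / "join_report.json")
    stage("import", sequences=len(seqs), specimens=len(specimens), joined=len(library))

    # qc + align
    profile = default_profile(config.profile_length)
    alignment, reports = bqc.align_records(library.sequences, profile)
    library.alignment = alignment
    bqc.qc_table(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    emit("qc_report", out / "qc_report.tsv")
    n_fail = sum(1 for r in reports if not r.passed)
    stage("qc", passed=len(alignment.ids), failed=n_fail)
    if len(alignment.ids) < 2:
        raise PipelineError("qc: fewer than 2 sequences passed")

    # distances
    dm = distance_matrix(alignment)
    dm.write_tsv(out / "distances.tsv")
    emit("distances", out / "distances.tsv")
    stage("distances", n=len(dm), flagged_pairs=len(dm.flagged_pairs))

    # tree
    if config.run_tree and len(dm) >= 4:
        tree = bootstrap_supports(alignment, reps=config.bootstrap_reps, seed=config.seed)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        emit("tree", out / "tree.nwk")
        stage("tree", leaves=len(dm), reps=config.bootstrap_reps, seed=config.seed)
    else:
        stage("tree", skipped=True)

    # cluster / bins
    meta_map = library.specimen_map()
    if config.bin_source == "metadata":
        missing = [i for i in dm.ids if not meta_map[i].bin_id]
        if missing:
            raise PipelineError(f"bin_source=metadata but no bin_id for: {missing[:5]}")
        assignment = {i: meta_map[i].bin_id for i in dm.ids}
        stage("cluster", source="metadata", clusters=len(set(assignment.values())))
    else:
        partition = resl_partition(dm, seed_threshold=config.seed_threshold)
        assignment = partition.assignment
        pd.DataFrame(
            sorted(assignment.items()), columns=["specimen_id", "motu_label"]
        ).to_csv(out / "partition.tsv", sep="\t", index=False)
        emit("partition", out / "partition.tsv")
        stage(
            "cluster",
            source="computed",
            clusters=partition.n_clusters(),
            silhouette=partition.silhouette,
            warnings=partition.warnings,
        )

    # concordance
    binned = [
        SpecimenRecord(
            specimen_id=m.specimen_id,
            species_label=m.species_label,
            label_rank=m.label_rank,
            is_reference=m.is_reference,
            suspect_misid=m.suspect_misid,
            country=m.country,
            bin_id=assignment[m.specimen_id],
        )
        for m in library.specimens
        if m.specimen_id in assignment
    ]
    results = classify_species(binned)
    counts = category_counts(results)
    stage("concordance", **counts)

    # summaries + report
    summaries = species_summary(dm, meta_map)
    gap = barcode_gap_table(summaries)
    gap.to_csv(out / "barcode_gap.tsv", sep="\t", index=False)
    emit("barcode_gap", out / "barcode_gap.tsv")
    sxh = specimens_vs_haplotypes(summaries, results)
    sxh.to_csv(out / "specimens_vs_haplotypes.tsv", sep="\t", index=False)
    emit("specimens_vs_haplotypes", out / "specimens_vs_haplotypes.tsv")
    table2 = summary_report(binned, results, dm, summaries)
    table2.to_csv(out / "species_report.tsv", sep="\t", index=False)
    emit("species_report", out / "species_report.tsv")
    stage("report", species=len(results), rows=len(table2))

    # identification of queries
    if config.queries_fasta:
        queries = bio.read_fasta(config.queries_fasta)
        id_results = identify_queries(
            library, queries, profile, seed_threshold=config.seed_threshold
        )
        table3 = query_report(id_results, meta_map)
        table3.to_csv(out / "query_report.tsv", sep="\t", index=False)
        emit("query_report", out / "query_report.tsv")
        stage(
            "identify",
            queries=len(queries),
            successes=sum(r.success for r in id_results),
            new_clusters=sum(r.is_new_cluster for r in id_results),
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def summary_report(binned_specimens, results, dm, summaries) -> pd.DataFrame:
    """Per-(species, bin) report: category, occupancy, within-bin and
    within-species divergence (percent, 2 decimals), countries."""
    assignment = {m.specimen_id: m.bin_id for m in binned_specimens}
    internal, _ = cluster_summary(dm, {i: assignment[i] for i in dm.ids})
    by_species = {s.species_label: s for s in summaries}
    meta_by_label = {}
    for m in binned_specimens:
        meta_by_label.setdefault(m.species_label, []).append(m)
    rows = []
    for r in results:
        s = by_species.get(r.species_label)
        for b in r.bins_occupied:
            n_occ = sum(
                1 for m in meta_by_label[r.species_label] if m.bin_id == b and not m.suspect_misid
            )
            countries = sorted(
                {
                    m.country
                    for m in meta_by_label[r.species_label]
                    if m.bin_id == b and m.country
                }
            )
            rows.append(
                {
                    "species_label": r.species_label,
                    "category": r.category,
                    "bin": f"{b}({n_occ})",
                    "within_bin_pct": ""
                    if internal.get(b) is None
                    else f"{100 * internal[b]:.2f}",
                    "within_species_pct": ""
                    if s is None or s.mean_intra is None
                    else f"{100 * s.mean_intra:.2f}",
                    "countries": "; ".join(countries),
                }
            )
    return pd.DataFrame(rows)


def query_report(id_results, specimens) -> pd.DataFrame:
    """Query identification table: assignment, success, nearest reference."""
    prov = provenance_report(id_results, specimens).set_index("query_id")["provenance"]
    rows = []
    for r in id_results:
        rows.append(
            {
                "query_id": r.query_id,
                "assigned_cluster": r.assigned_cluster or "",
                "cluster_category": r.cluster_category,
                "co_member_species": "; ".join(r.co_member_species),
                "success": int(r.success),
                "is_new_cluster": int(r.is_new_cluster),
                "nearest_reference_id": r.nearest_reference_id or "",
                "nearest_reference_pct": ""
                if r.nearest_reference_distance is None
                else f"{100 * r.nearest_reference_distance:.2f}",
                "provenance": prov.get(r.query_id, ""),
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)


def fixture_report() -> pd.DataFrame:
    """Concordance of the packaged incidence fixture (category per species)."""
    table = bio.load_incidence_fixture()
    results = classify_species(bio.incidence_to_specimens(table))
    counts = category_counts(results)
    df = pd.DataFrame(
        [
            {
                "species_label": r.species_label,
                "category": r.category,
                "n_bins": len(r.bins_occupied),
                "provisional": int(r.provisional),
            }
            for r in results
        ]
    )
    df.attrs["category_counts"] = counts
    return df
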