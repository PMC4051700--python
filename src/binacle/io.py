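"""Sequence and specimen-metadata I/O for barcode reference libraries.

Sequences travel as FASTA (via Biopython), specimen metadata as
tab-separated tables with a fixed documented header.  The two are joined
on exact id match into a :class:`ReferenceLibrary`; ids present on only
one side are reported as orphans, never silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_GAP = set("ACGTRYSWKMBDHVN-")

#: ranks a specimen label can carry; ``provisional`` covers open-nomenclature
#: labels such as "C. cf. marulius" which are species-like but excluded from
#: species tallies.
LABEL_RANKS = ("species", "genus_only", "hybrid", "provisional")

# BOLD-style export dialects use varying column names; normalized here.
COLUMN_ALIASES = {
    "sample id": "specimen_id",
    "sample_id": "specimen_id",
    "process id": "specimen_id",
    "processid": "specimen_id",
    "species name": "species_label",
    "species_name": "species_label",
    "identification": "species_label",
    "bin": "bin_id",
    "bin uri": "bin_id",
    "bin_uri": "bin_id",
    "country/ocean": "country",
}


class BarcodeIOError(ValueError):
    """Raised for malformed sequence or metadata inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    source: str = "local"  # local | imported

    def __post_init__(self):
        if not self.id:
            raise BarcodeIOError("sequence record with empty id")
        if not self.seq:
            raise BarcodeIOError(f"sequence {self.id!r} is empty")
        bad = [(i, c) for i, c in enumerate(self.seq) if c not in IUPAC_GAP]
        if bad:
            i, c = bad[0]
            raise BarcodeIOError(
                f"sequence {self.id!r}: non-IUPAC character {c!r} at position {i}"
            )


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    species_label: str
    label_rank: str = "species"
    is_reference: bool = False
    suspect_misid: bool = False
    country: str = ""
    bin_id: str = ""
    voucher_retained: bool = True

    def __post_init__(self):
        if self.label_rank not in LABEL_RANKS:
            raise BarcodeIOError(
                f"specimen {self.specimen_id!r}: unknown label rank {self.label_rank!r}"
            )


@dataclass
class ReferenceLibrary:
    """Sequences and metadata joined 1:1 on id."""

    records: list  # list[(SequenceRecord, SpecimenRecord)]
    alignment: object = None  # Optional AlignedMatrix, attached by coi_qc

    def __len__(self):
        return len(self.records)

    @property
    def sequences(self):
        return [s for s, _ in self.records]

    @property
    def specimens(self):
        return [m for _, m in self.records]

    def specimen_map(self):
        return {m.specimen_id: m for _, m in self.records}


@dataclass(frozen=True)
class IncidenceRow:
    species_label: str
    bin_id: str
    specimen_count: int
    label_rank: str = "species"
    suspect_misid: bool = False
    is_reference_bin: bool = True
    table_category: str = ""
    reference_country: str = ""
    detected_in: str = ""
    occupancy_notes: str = ""


@dataclass
class IncidenceTable:
    rows: list

    def __post_init__(self):
        seen = set()
        for r in self.rows:
            if r.specimen_count < 1:
                raise BarcodeIOError(
                    f"incidence row {r.species_label}/{r.bin_id}: count < 1"
                )
            key = (r.species_label, r.bin_id)
            if key in seen:
                raise BarcodeIOError(f"duplicate incidence row {key}")
            seen.add(key)

    def bin_ids(self):
        return sorted({r.bin_id for r in self.rows})

    def bin_totals(self):
        totals = {}
        for r in self.rows:
            totals[r.bin_id] = totals.get(r.bin_id, 0) + r.specimen_count
        return totals


def _normalize_seq(s: str) -> str:
    return str(s).upper().replace("U", "T")


def read_fasta(path) -> list:
    """Read FASTA into :class:`SequenceRecord` list, preserving file order.

    Sequences are uppercased and RNA U is mapped to T.  Duplicate ids,
    empty files and non-IUPAC characters are hard errors.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise BarcodeIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=_normalize_seq(rec.seq)))
    if not records:
        raise BarcodeIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


def infer_label_rank(label: str) -> str:
    """Infer rank from a taxon label string.

    "Genus sp."/genus-only labels -> genus_only; "A x B" crosses -> hybrid;
    "cf." open nomenclature -> provisional; anything else -> species.
    """
    label = label.strip()
    low = label.lower()
    if re.search(r"\bcf\.", low):
        return "provisional"
    if re.search(r"\)?\s+x\s+", low):
        return "hybrid"
    if re.search(r"\bsp(p)?\.?$", low) or re.search(r"\bspecies\b", low):
        return "genus_only"
    if len(label.split()) < 2:
        return "genus_only"
    return "species"


_TRUE = {"1", "true", "yes", "y", "t"}


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if pd.isna(v):
        return False
    return str(v).strip().lower() in _TRUE


def read_specimen_table(path) -> list:
    """Read a tab-separated specimen metadata table.

    Required columns: specimen_id, species_label (BOLD-style aliases are
    normalized).  Optional columns take documented defaults; label_rank is
    inferred from the label when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [COLUMN_ALIASES.get(c.strip().lower(), c.strip()) for c in df.columns]
    missing = [c for c in ("specimen_id", "species_label") if c not in df.columns]
    if missing:
        raise BarcodeIOError(f"specimen table {path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        label = str(row["species_label"]).strip()
        rank = str(row.get("label_rank", "") or "").strip() or infer_label_rank(label)
        out.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]).strip(),
                species_label=label,
                label_rank=rank,
                is_reference=_as_bool(row.get("is_reference", False)),
                suspect_misid=_as_bool(row.get("suspect_misid", False)),
                country=str(row.get("country", "") or "").strip(),
                bin_id=str(row.get("bin_id", "") or "").strip(),
                voucher_retained=_as_bool(row.get("voucher_retained", True))
                if "voucher_retained" in df.columns
                else True,
            )
        )
    ids = [r.specimen_id for r in out]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise BarcodeIOError(f"duplicate specimen ids: {sorted(dupes)}")
    return out


def write_specimen_table(specimens: Iterable[SpecimenRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": m.specimen_id,
                "species_label": m.species_label,
                "label_rank": m.label_rank,
                "is_reference": int(m.is_reference),
                "suspect_misid": int(m.suspect_misid),
                "country": m.country,
                "bin_id": m.bin_id,
                "voucher_retained": int(m.voucher_retained),
            }
            for m in specimens
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def build_library(seqs, specimens):
    """Inner-join sequences and specimens on id.

    Returns ``(library, report)`` where the report lists orphan ids on
    either side.  Orphans are reported, never fatal.
    """
    meta = {m.specimen_id: m for m in specimens}
    used = set()
    records = []
    orphan_seqs = []
    for s in seqs:
        key = s.id.strip()
        if key in meta:
            records.append((s, meta[key]))
            used.add(key)
        else:
            orphan_seqs.append(s.id)
    orphan_meta = [m.specimen_id for m in specimens if m.specimen_id not in used]
    report = {"orphan_sequences": orphan_seqs, "orphan_specimens": orphan_meta}
    return ReferenceLibrary(records=records), report


def load_incidence_fixture(path=None) -> IncidenceTable:
    """Load the packaged species-by-BIN incidence table.

    The table transcribes the published snakehead calibration: every
    (species label, BIN, specimen count) row, with the heterogeneous-cluster
    occupancies spelled out per occupant label and the curation flags
    (suspected misidentifications) that the published concordance
    assignments presume.
    """
    if path is None:
        ref = resources.files("binacle").joinpath("data/table2_incidence.tsv")
        with resources.as_file(ref) as p:
            return load_incidence_fixture(p)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # missing/corrupt fixture is a hard error
        raise BarcodeIOError(f"cannot read incidence table {path}: {exc}") from exc
    required = {"species_label", "bin_id", "specimen_count"}
    if not required <= set(df.columns):
        raise BarcodeIOError(f"incidence table {path}: missing {required - set(df.columns)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            IncidenceRow(
                species_label=r["species_label"].strip(),
                bin_id=r["bin_id"].strip(),
                specimen_count=int(r["specimen_count"]),
                label_rank=(r.get("label_rank") or "species").strip(),
                suspect_misid=_as_bool(r.get("suspect_misid", "0")),
                is_reference_bin=_as_bool(r.get("is_reference_bin", "1")),
                table_category=(r.get("table_category") or "").strip(),
                reference_country=(r.get("reference_country") or "").strip(),
                detected_in=(r.get("detected_in") or "").strip(),
                occupancy_notes=(r.get("occupancy_notes") or "").strip(),
            )
        )
    return IncidenceTable(rows=rows)


def incidence_to_specimens(table: IncidenceTable) -> list:
    """Expand incidence rows into one pseudo-specimen per counted individual.

    Lets the concordance classifier run on published species-by-cluster
    tallies exactly as it runs on real specimen metadata.
    """
    out = []
    for r in table.rows:
        for k in range(r.specimen_count):
            out.append(
                SpecimenRecord(
                    specimen_id=f"{r.bin_id}|{r.species_label}|{k}",
                    species_label=r.species_label,
                    label_rank=r.label_rank,
                    is_reference=r.is_reference_bin,
                    suspect_misid=r.suspect_misid,
                    country=r.reference_country,
                    bin_id=r.bin_id,
                )
            )
    return out
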