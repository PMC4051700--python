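"""COI sequence quality control and translation-guided alignment.

The barcode region of COI is expected to be an indel-free open reading
frame under the vertebrate mitochondrial code; a stop codon or a
frameshift relative to the reference amino-acid profile is the classic
signature of a nuclear pseudogene (NUMT) and fails QC.  Alignment is
therefore ungapped: each sequence is translated in its detected frame and
slid along a reference amino-acid profile to find its codon offset, which
fixes its column placement in an equal-length nucleotide matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .io import SequenceRecord

#: NCBI translation table for the vertebrate mitochondrial code.
DEFAULT_CODE_TABLE = 2

MIN_CALLABLE_LENGTH = 60
#: below this amino-acid identity to the profile a record is treated as
#: frameshifted/non-homologous (conservative default, configurable).
DEFAULT_IDENTITY_THRESHOLD = 0.5


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    specimen_id: str
    frame: Optional[int]
    stop_codons: int
    has_indel_vs_profile: bool
    ambiguous_fraction: float
    offset: Optional[int] = None
    profile_identity: Optional[float] = None

    @property
    def passed(self) -> bool:
        return self.stop_codons == 0 and not self.has_indel_vs_profile


@dataclass
class AlignedMatrix:
    """Equal-length nucleotide matrix; rows padded with '-' at both ends."""

    ids: list
    rows: list
    offsets: list

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise QCError(f"aligned rows of unequal length: {sorted(lengths)}")
        if any(o < 0 for o in self.offsets):
            raise QCError("negative alignment offset")

    @property
    def columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def unpadded(self, i: int) -> str:
        return self.rows[i].strip("-")

    def subset(self, ids):
        idx = {j: i for i, j in enumerate(self.ids)}
        keep = [idx[i] for i in ids]
        return AlignedMatrix(
            ids=[self.ids[i] for i in keep],
            rows=[self.rows[i] for i in keep],
            offsets=[self.offsets[i] for i in keep],
        )


def translate_mito(seq: str, frame: int, table: int = DEFAULT_CODE_TABLE) -> str:
    """Translate ``seq`` from ``frame`` under the (vertebrate mito) code.

    One letter per complete codon; stops are '*'; ambiguity codes that do
    not resolve to a unique amino acid give 'X'.  Trailing partial codons
    are dropped.
    """
    if frame not in (0, 1, 2):
        raise QCError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=table))


def detect_reading_frame(seq: str, table: int = DEFAULT_CODE_TABLE):
    """Return ``(frame, stops_per_frame)``.

    The frame is the smallest index whose translation contains no stop
    codon, or None when every frame contains stops (pseudogene signal).
    """
    if len(seq) < MIN_CALLABLE_LENGTH:
        raise QCError(
            f"sequence too short to call a reading frame ({len(seq)} < {MIN_CALLABLE_LENGTH} nt)"
        )
    stops = tuple(translate_mito(seq, f, table).count("*") for f in (0, 1, 2))
    frame = next((f for f in (0, 1, 2) if stops[f] == 0), None)
    return frame, stops


#: offsets whose profile overlap is shorter than this many residues are not
#: considered (a two-residue perfect overlap must not outscore a long match)
MIN_AA_OVERLAP = 20


def align_to_profile(
    seq: str,
    frame: int,
    profile: str,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    table: int = DEFAULT_CODE_TABLE,
):
    """Best ungapped placement of a sequence against an amino-acid profile.

    Returns ``(nt_offset, identity)`` where the offset is the number of
    nucleotide columns preceding the sequence in profile coordinates
    (column 0 = first base of profile codon 0).  The offset maximizing
    amino-acid identity over the overlap wins; ties break toward the
    smaller offset.  Identity below the threshold means no reliable
    ungapped placement exists (frameshift or non-homologous sequence) and
    the caller should flag the record rather than rescue it with gaps.
    """
    aa = translate_mito(seq, frame, table)
    if not aa:
        raise QCError("empty translation")
    min_overlap = min(MIN_AA_OVERLAP, len(aa), len(profile))
    best_k, best_ident = 0, -1.0
    max_k = max(len(profile) - 1, 0)
    for k in range(0, max_k + 1):
        overlap = min(len(aa), len(profile) - k)
        if overlap < min_overlap:
            break
        matches = sum(1 for i in range(overlap) if aa[i] == profile[k + i])
        ident = matches / overlap
        if ident > best_ident:
            best_k, best_ident = k, ident
    nt_offset = 3 * best_k - frame
    if nt_offset < 0:
        # sequence starts mid-codon before the profile window; clip the
        # dangling bases so column coordinates stay nonnegative
        nt_offset = 0
    return nt_offset, best_ident


def _ambiguous_fraction(seq: str) -> float:
    plain = sum(1 for c in seq if c in "ACGT")
    return 1.0 - plain / len(seq) if seq else 0.0


FRAMESHIFT_CHUNK = 150


def check_frameshift(
    seq: str,
    profile: str,
    chunk: int = FRAMESHIFT_CHUNK,
    table: int = DEFAULT_CODE_TABLE,
) -> bool:
    """Detect a frameshift by chunked placement consistency.

    The sequence is cut into ~``chunk``-nt pieces, each placed independently
    against the profile (own frame, own best offset).  In an indel-free
    sequence the recovered profile coordinates advance exactly with the cut
    positions; an insertion or deletion shifts every downstream chunk off
    register.  This catches frameshifts that a whole-sequence identity test
    misses (an ungapped aligner happily re-anchors the longer clean side).
    """
    if len(seq) < 2 * chunk:
        return False
    cuts = list(range(0, len(seq), chunk))
    if len(seq) - cuts[-1] < MIN_CALLABLE_LENGTH:
        cuts.pop()
    offsets = []
    for c in cuts:
        piece = seq[c : c + chunk] if c != cuts[-1] else seq[c:]
        # short pieces can be stop-free in a wrong frame by chance, so the
        # frame is chosen by profile identity, not by stop count
        o, _ = max(
            (align_to_profile(piece, f, profile, table=table) for f in (0, 1, 2)),
            key=lambda t: t[1],
        )
        offsets.append(o)
    return any(offsets[i] - offsets[0] != cuts[i] for i in range(1, len(cuts)))


def qc_record(
    record: SequenceRecord,
    profile: str,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    table: int = DEFAULT_CODE_TABLE,
) -> QCReport:
    """Run frame detection plus profile placement on one record."""
    frame, stops = detect_reading_frame(record.seq, table)
    if frame is None:
        # no clean frame: align in the least-bad frame so frameshifts are
        # still distinguishable from plain stop-codon pseudogenes
        probe = min((0, 1, 2), key=lambda f: stops[f])
        n_stops = stops[probe]
    else:
        probe = frame
        n_stops = 0
    offset, ident = align_to_profile(record.seq, probe, profile, identity_threshold, table)
    has_indel = ident < identity_threshold or check_frameshift(record.seq, profile, table=table)
    return QCReport(
        specimen_id=record.id,
        frame=frame,
        stop_codons=n_stops,
        has_indel_vs_profile=has_indel,
        ambiguous_fraction=_ambiguous_fraction(record.seq),
        offset=offset if not has_indel else None,
        profile_identity=ident,
    )


def align_records(
    records,
    profile: str,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    table: int = DEFAULT_CODE_TABLE,
):
    """QC a batch and build the equal-length matrix from the passers.

    Returns ``(AlignedMatrix, list[QCReport])``; failed records appear in
    the reports but not in the matrix.
    """
    reports = []
    placed = []
    for rec in records:
        rep = qc_record(rec, profile, identity_threshold, table)
        reports.append(rep)
        if rep.passed:
            placed.append((rec.id, rec.seq, rep.offset))
    if not placed:
        return AlignedMatrix(ids=[], rows=[], offsets=[]), reports
    width = max(off + len(seq) for _, seq, off in placed)
    ids, rows, offsets = [], [], []
    for rid, seq, off in placed:
        ids.append(rid)
        rows.append("-" * off + seq + "-" * (width - off - len(seq)))
        offsets.append(off)
    return AlignedMatrix(ids=ids, rows=rows, offsets=offsets), reports


def composition(records) -> dict:
    """Mean nucleotide frequencies over unambiguous bases, pooled.

    Reported in T, C, G, A order (the convention of barcode survey
    papers); frequencies sum to 1.
    """
    seqs = [r.seq if hasattr(r, "seq") else r for r in records]
    if not seqs:
        raise QCError("composition of empty input")
    counts = {b: 0 for b in "TCGA"}
    for s in seqs:
        for b in s:
            if b in counts:
                counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise QCError("no unambiguous bases in input")
    return {b: counts[b] / total for b in "TCGA"}


def qc_table(reports) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "frame": "" if r.frame is None else r.frame,
                "stop_codons": r.stop_codons,
                "has_indel_vs_profile": int(r.has_indel_vs_profile),
                "ambiguous_fraction": round(r.ambiguous_fraction, 6),
                "passed": int(r.passed),
            }
            for r in reports
        ]
    )
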