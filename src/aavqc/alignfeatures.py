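"""Per-read alignment features for DNA-state classification.

The classifier looks at three things per primary alignment: how much of
the query is soft/hard-clipped, how many supplementary alignments the
read has (from the SA tag), and where the aligned segments sit on the
reference.  This module parses SAM/BAM records with pysam and derives
those features into a plain :class:`AlignedRead`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_ALIGN_OPS = set("M=X")


def split_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_reference_length(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string (M/D/N/=/X)."""
    return sum(n for n, op in split_cigar(cigar) if op in _REF_OPS)


def cigar_query_length(cigar: str) -> int:
    """Full query length implied by a CIGAR, clips (soft and hard) included."""
    return sum(n for n, op in split_cigar(cigar) if op in _QUERY_OPS or op == "H")


def cigar_clips(cigar: str) -> tuple[int, int]:
    """(left, right) clipped query bases; soft and hard clips both count."""
    ops = split_cigar(cigar)
    left = right = 0
    i = 0
    while i < len(ops) and ops[i][1] in "SH":
        left += ops[i][0]
        i += 1
    j = len(ops) - 1
    while j >= i and ops[j][1] in "SH":
        right += ops[j][0]
        j -= 1
    return left, right


@dataclass(frozen=True)
class SupplementaryAlignment:
    """One entry of the primary record's SA tag."""

    ref_name: str
    ref_start: int  # 0-based
    strand: str
    cigar: str

    @property
    def ref_end(self) -> int:
        return self.ref_start + cigar_reference_length(self.cigar)

    def query_interval(self, read_length: int) -> tuple[int, int]:
        """Query span in original-read orientation covered by this entry."""
        left, right = cigar_clips(self.cigar)
        qlen = cigar_query_length(self.cigar) - left - right
        if self.strand == "+":
            return left, left + qlen
        return right, right + qlen


@dataclass(frozen=True)
class AlignedRead:
    """Primary alignment record reduced to classifier features.

    ``clip_left``/``clip_right`` are in record orientation (as stored);
    ``read_length`` is the full query length including hard clips.
    """

    read_id: str
    read_length: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    clip_left: int
    clip_right: int
    aligned_bases: int
    insertions: int = 0
    supplementary: tuple[SupplementaryAlignment, ...] = ()

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        accounted = self.clip_left + self.clip_right + self.aligned_bases + self.insertions
        if accounted > self.read_length:
            raise ValueError(
                f"CIGAR accounts for {accounted} query bases but read_length "
                f"is {self.read_length}"
            )

    def query_interval(self) -> tuple[int, int]:
        """Primary-aligned query span in original-read orientation."""
        qlen = self.aligned_bases + self.insertions
        if self.strand == "+":
            return self.clip_left, self.clip_left + qlen
        return self.clip_right, self.clip_right + qlen


def softclip_fraction(read: AlignedRead) -> float:
    """Clipped query bases of the primary alignment over full read length."""
    if read.read_length <= 0:
        raise ValueError("read_length must be positive")
    return (read.clip_left + read.clip_right) / read.read_length


def supplementary_count(read: AlignedRead) -> int:
    """Number of (de-duplicated) SA-tag entries on the primary record."""
    return len(read.supplementary)


def group_span(read: AlignedRead) -> tuple[int, int]:
    """Leftmost/rightmost reference position over primary plus
    supplementary alignments on the primary's reference.

    A fold-back read's two halves sit on primary + supplementary
    records, so the primary span alone under-reports how much of the
    genome the molecule covered.
    """
    left, right = read.ref_start, read.ref_end
    for sa in read.supplementary:
        if sa.ref_name == read.ref_name:
            left = min(left, sa.ref_start)
            right = max(right, sa.ref_end)
    return left, right


def _parse_sa_tag(sa_tag: str, read_id: str) -> tuple[SupplementaryAlignment, ...]:
    entries: list[SupplementaryAlignment] = []
    seen: set[tuple[str, int, str]] = set()
    for raw in sa_tag.rstrip(";").split(";"):
        if not raw:
            continue
        parts = raw.split(",")
        if len(parts) < 4:
            log.warning("read %s: malformed SA entry %r dropped", read_id, raw)
            continue
        try:
            entry = SupplementaryAlignment(
                ref_name=parts[0],
                ref_start=int(parts[1]) - 1,
                strand=parts[2],
                cigar=parts[3],
            )
            entry.ref_end  # validates the CIGAR
        except (ValueError, IndexError):
            log.warning("read %s: malformed SA entry %r dropped", read_id, raw)
            continue
        key = (entry.ref_name, entry.ref_start, entry.strand)
        if key in seen:  # robust when a BAM duplicates SA entries
            continue
        seen.add(key)
        entries.append(entry)
    return tuple(entries)


def from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    """Convert a primary pysam record into an :class:`AlignedRead`."""
    if seg.is_unmapped or seg.is_secondary:
        raise ValueError("secondary/unmapped records are not accepted")
    if seg.cigartuples is None:
        raise ValueError("record has no CIGAR")
    cigar = seg.cigarstring
    clip_left, clip_right = cigar_clips(cigar)
    aligned = sum(n for n, op in split_cigar(cigar) if op in _ALIGN_OPS)
    insertions = sum(n for n, op in split_cigar(cigar) if op == "I")
    read_length = cigar_query_length(cigar)
    sa = seg.get_tag("SA") if seg.has_tag("SA") else ""
    return AlignedRead(
        read_id=seg.query_name,
        read_length=read_length,
        ref_name=seg.reference_name,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end,
        strand="-" if seg.is_reverse else "+",
        clip_left=clip_left,
        clip_right=clip_right,
        aligned_bases=aligned,
        insertions=insertions,
        supplementary=_parse_sa_tag(sa, seg.query_name),
    )


def parse_record(
    sam_line: str | pysam.AlignedSegment,
    header: pysam.AlignmentHeader | None = None,
) -> AlignedRead:
    """Parse one SAM line (or pysam record) into an :class:`AlignedRead`.

    When a bare line is given without a header, a throwaway header is
    built from the line's reference name so pysam can parse it.
    """
    if isinstance(sam_line, pysam.AlignedSegment):
        return from_pysam(sam_line)
    fields = sam_line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise ValueError("not a SAM alignment line")
    if header is None:
        rname = fields[2]
        header = pysam.AlignmentHeader.from_references([rname], [1 << 29])
    seg = pysam.AlignedSegment.fromstring(sam_line.rstrip("\n"), header)
    return from_pysam(seg)


def read_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped (the SA
    tag of each primary record carries the supplementary information
    the classifier needs); records without a CIGAR are skipped with a
    warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.cigartuples is None:
                log.warning("read %s: no CIGAR, skipped", seg.query_name)
                continue
            yield from_pysam(seg)


def features_table(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    """Per-read feature table (one row per primary alignment)."""
    rows = []
    for r in reads:
        left, right = group_span(r)
        rows.append(
            {
                "read_id": r.read_id,
                "ref_name": r.ref_name,
                "read_length": r.read_length,
                "clip_fraction": softclip_fraction(r),
                "n_supp": supplementary_count(r),
                "span_left": left,
                "span_right": right,
                "aligned_bases": r.aligned_bases,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "ref_name",
            "read_length",
            "clip_fraction",
            "n_supp",
            "span_left",
            "span_right",
            "aligned_bases",
        ],
    )
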