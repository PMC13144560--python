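"""Reference sequences and annotations for vector-genome QC.

A :class:`ReferenceModel` holds the vector plasmid together with the
contaminant reference set the reads were aligned against, plus the
coordinate annotations (expected genome boundaries, ITR intervals) that
the DNA-state classifier queries.  All coordinates are 0-based,
half-open, following the BED convention of the annotation files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: Recognised reference categories.  ``vector`` is mandatory; the others
#: mirror the contaminant panel a producer-cell-line process worries
#: about (host genome, E. coli from plasmid production, packaging
#: plasmids) with ``other`` as catch-all.
CATEGORIES = ("vector", "human", "ecoli", "repcaphelper", "other")


@dataclass(frozen=True)
class ReferenceModel:
    """Reference set plus vector-genome annotations.

    Parameters
    ----------
    references
        Tuples ``(name, sequence, category)``.  ``sequence`` may be an
        empty string for contaminant references used only as alignment
        targets (the classifier never needs their bases).
    genome_start, genome_end
        0-based half-open span of the expected vector genome on the
        vector reference.
    itr_intervals
        ``[start, end)`` intervals of the inverted terminal repeats,
        on the vector reference.
    """

    references: tuple[tuple[str, str, str], ...]
    genome_start: int
    genome_end: int
    itr_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.references]
        if len(names) != len(set(names)):
            raise ValueError("reference names must be unique")
        for name, _, cat in self.references:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for reference {name!r}")
        if not any(cat == "vector" for _, _, cat in self.references):
            raise ValueError("a vector reference is required")
        if not self.genome_start < self.genome_end:
            raise ValueError("genome_start must be < genome_end")
        for start, end in self.itr_intervals:
            if not (self.genome_start <= start < end <= self.genome_end):
                raise ValueError(
                    f"ITR interval [{start}, {end}) outside genome "
                    f"[{self.genome_start}, {self.genome_end})"
                )

    @property
    def genome_length(self) -> int:
        """Expected vector genome length L in nucleotides."""
        return self.genome_end - self.genome_start

    @property
    def vector_name(self) -> str:
        return next(name for name, _, cat in self.references if cat == "vector")

    @property
    def vector_sequence(self) -> str:
        return next(seq for _, seq, cat in self.references if cat == "vector")

    def category_of(self, ref_name: str) -> str:
        for name, _, cat in self.references:
            if name == ref_name:
                return cat
        raise KeyError(f"unknown reference {ref_name!r}")

    @property
    def reference_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq, _ in self.references}


def load_references(
    fasta_path: str | Path,
    annotation_path: str | Path,
    categories: Mapping[str, str] | None = None,
) -> ReferenceModel:
    """Build a validated :class:`ReferenceModel` from FASTA + BED.

    The BED file must contain, on the vector reference, one interval
    named ``genome`` (the expected genome span) and at least one named
    ``ITR``.  ``categories`` maps reference names to categories; names
    not listed default to ``other``, and the reference carrying the
    ``genome`` annotation defaults to ``vector``.

    Raises
    ------
    ValueError
        On a missing vector reference, duplicate names, or ITR
        intervals outside the genome span.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")

    genome_span: tuple[str, int, int] | None = None
    itrs: list[tuple[str, int, int]] = []
    with open(annotation_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line needs >=4 columns: {line!r}")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if name.lower() == "genome":
                genome_span = (chrom, start, end)
            elif name.upper().startswith("ITR"):
                itrs.append((chrom, start, end))
    if genome_span is None:
        raise ValueError("annotation must contain a 'genome' interval")
    if not itrs:
        raise ValueError("annotation must contain at least one ITR interval")

    categories = dict(categories or {})
    vector_chrom = genome_span[0]
    categories.setdefault(vector_chrom, "vector")

    refs = tuple(
        (rec.id, str(rec.seq).upper(), categories.get(rec.id, "other"))
        for rec in records
    )
    for chrom, _, _ in itrs:
        if chrom != vector_chrom:
            raise ValueError(f"ITR interval on {chrom!r}, not on vector {vector_chrom!r}")
    return ReferenceModel(
        references=refs,
        genome_start=genome_span[1],
        genome_end=genome_span[2],
        itr_intervals=tuple((s, e) for _, s, e in itrs),
    )


def write_annotations(model: ReferenceModel, bed_path: str | Path) -> None:
    """Write genome span and ITR intervals back to BED (round-trip aid)."""
    with open(bed_path, "w") as fh:
        name = model.vector_name
        fh.write(f"{name}\t{model.genome_start}\t{model.genome_end}\tgenome\n")
        for i, (s, e) in enumerate(model.itr_intervals, 1):
            fh.write(f"{name}\t{s}\t{e}\tITR{i}\n")


def position_in_itr(model: ReferenceModel, pos: int, tolerance: int = 0) -> bool:
    """True iff ``pos`` lies within an ITR interval expanded by ±tolerance.

    Intervals are half-open, so the expanded test is
    ``start - tolerance <= pos < end + tolerance``.  Out-of-range
    positions simply return False.
    """
    if pos < 0:
        return False
    return any(s - tolerance <= pos < e + tolerance for s, e in model.itr_intervals)


def distance_to_itr(model: ReferenceModel, pos: int) -> int:
    """Distance in nt from ``pos`` to the nearest ITR interval (0 if inside)."""
    best = None
    for s, e in model.itr_intervals:
        if s <= pos < e:
            return 0
        d = s - pos if pos < s else pos - (e - 1)
        best = d if best is None else min(best, d)
    if best is None:
        raise ValueError("model has no ITR intervals")
    return best
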