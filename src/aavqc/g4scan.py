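"""Putative G-quadruplex (QGRS) motif scanning.

A quadruplex-forming G-rich sequence is four G-runs of equal length
``g`` separated by three loops:

    G{g} N{l1} G{g} N{l2} G{g} N{l3} G{g}

The scanner enumerates *every* decomposition — a long G-run spawns all
eligible sub-runs, which is why "including overlaps" counts run into
the thousands on GC-rich genomes — and a greedy selection by G-score
reduces them to a non-overlapping subset.

The G-score is comparative only: it orders candidates by likelihood of
forming a stable quadruplex.  The exact formula used here encodes, in
strict lexicographic priority, (1) more tetrads, (2) shorter total loop
length, (3) more equal loop lengths:

    score = 10^6 * g - 10^3 * (l1 + l2 + l3) - (max(l) - min(l))

Scores from different parameter sets are comparable only in ordering,
never in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_VALID = set("ACGTN")


@dataclass(frozen=True)
class QgrsParams:
    """Scan parameters.

    Defaults are the conventional web-tool settings for a permissive
    scan: candidates at most 30 nt long, G-groups of at least two Gs,
    loops of 0–36 nt.  Note the loop bound is mostly decorative at
    these defaults — the 30-nt length cap dominates, since a 36-nt
    loop can never fit.
    """

    max_length: int = 30
    min_g_group: int = 2
    loop_min: int = 0
    loop_max: int = 36

    def __post_init__(self) -> None:
        if self.max_length < 4 * self.min_g_group:
            raise ValueError("max_length must fit four minimal G-groups")
        if self.loop_min < 0 or self.loop_max < self.loop_min:
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.min_g_group < 1:
            raise ValueError("min_g_group must be >= 1")


@dataclass(frozen=True)
class QgrsHit:
    """One candidate quadruplex: position, tetrad count, loops, score."""

    start: int
    g_run: int
    loops: tuple[int, int, int]
    score: int

    @property
    def total_length(self) -> int:
        return 4 * self.g_run + sum(self.loops)

    @property
    def end(self) -> int:
        return self.start + self.total_length

    def overlaps(self, other: "QgrsHit") -> bool:
        return self.start < other.end and other.start < self.end


def g_score(g_run: int, loops: Sequence[int]) -> int:
    """Lexicographic G-score: tetrads, then total loop, then equality."""
    total = sum(loops)
    spread = max(loops) - min(loops)
    return 10**6 * g_run - 10**3 * total - spread


def find_qgrs(sequence: str, params: QgrsParams | None = None) -> list[QgrsHit]:
    """All QGRS candidates in ``sequence``, overlapping ones included.

    Every distinct decomposition ``(start, g, l1, l2, l3)`` with four
    G-runs of equal length ``g >= min_g_group``, loops within
    ``[loop_min, loop_max]`` and total length at most ``max_length`` is
    returned once, ordered by start then length.  ``N`` is allowed in
    loops but never counts as G.
    """
    params = params or QgrsParams()
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError(f"invalid characters: {sorted(set(seq) - _VALID)}")
    n = len(seq)
    # grun[i] = length of the maximal G-run starting at i
    grun = np.zeros(n + 1, dtype=int)
    for i in range(n - 1, -1, -1):
        if seq[i] == "G":
            grun[i] = grun[i + 1] + 1

    p = params
    g_cap = p.max_length // 4
    hits: list[QgrsHit] = []
    for s in range(n):
        for g in range(p.min_g_group, min(int(grun[s]), g_cap) + 1):
            budget = min(p.max_length - 4 * g, n - s - 4 * g)
            if budget < 3 * p.loop_min:
                continue
            for l1 in range(p.loop_min, min(p.loop_max, budget - 2 * p.loop_min) + 1):
                p2 = s + g + l1
                if grun[p2] < g:
                    continue
                rem1 = budget - l1
                for l2 in range(p.loop_min, min(p.loop_max, rem1 - p.loop_min) + 1):
                    p3 = p2 + g + l2
                    if grun[p3] < g:
                        continue
                    rem2 = rem1 - l2
                    for l3 in range(p.loop_min, min(p.loop_max, rem2) + 1):
                        p4 = p3 + g + l3
                        if grun[p4] < g:
                            continue
                        hits.append(
                            QgrsHit(
                                start=s,
                                g_run=g,
                                loops=(l1, l2, l3),
                                score=g_score(g, (l1, l2, l3)),
                            )
                        )
    hits.sort(key=lambda h: (h.start, h.total_length, h.g_run, h.loops))
    return hits


def select_nonoverlapping(hits: Iterable[QgrsHit]) -> list[QgrsHit]:
    """Greedy non-overlapping subset, best G-score first.

    Ties break to the leftmost, then the shortest candidate.  Returned
    in genomic order.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.total_length))
    kept: list[QgrsHit] = []
    for hit in ordered:
        if all(not hit.overlaps(k) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def hits_table(hits: Sequence[QgrsHit], selected: Sequence[QgrsHit] = ()) -> pd.DataFrame:
    """Tabulate hits for CSV export, flagging the non-overlapping subset."""
    sel = set((h.start, h.g_run, h.loops) for h in selected)
    return pd.DataFrame(
        [
            {
                "start": h.start,
                "length": h.total_length,
                "g_run": h.g_run,
                "loop1": h.loops[0],
                "loop2": h.loops[1],
                "loop3": h.loops[2],
                "score": h.score,
                "selected": (h.start, h.g_run, h.loops) in sel,
            }
            for h in hits
        ],
        columns=["start", "length", "g_run", "loop1", "loop2", "loop3", "score", "selected"],
    )


def scan_summary(sequence: str, params: QgrsParams | None = None) -> dict:
    """Overlapping and non-overlapping counts plus the best score."""
    hits = find_qgrs(sequence, params)
    selected = select_nonoverlapping(hits)
    return {
        "n_overlapping": len(hits),
        "n_nonoverlapping": len(selected),
        "max_score": max((h.score for h in hits), default=None),
    }
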