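"""DNA-state classification of vector-mapped long reads.

Reads from an rAAV sequencing library fall into a small set of DNA
states determined by how the second strand was made:

* **duplex** — annealed plus/minus genome strands; the read maps
  near-fully, with almost no soft-clipping.
* **fill-up** — the genome's own 3' ITR primed second-strand synthesis,
  yielding a palindromic fold-back molecule of about twice the fragment
  length.  The primary alignment covers one half (about 50 % clipping),
  one supplementary alignment covers the other, and the fold point —
  the symmetry axis — lies in an ITR.
* **snapback** — same fold-back geometry, but folded at some internal
  secondary structure, so the symmetry axis is *not* in an ITR.
* **multimer** — the read splits into many supplementary alignments at
  non-adjacent reference positions (chimera or rolling-hairpin
  product).

The thresholds live in :class:`ClassifierConfig`; the rule engine is
the sklearn-style :class:`DnaStateClassifier`.  Reads falling in the
gaps between the rules (e.g. 65 % clipping, or 2–3 supplementary
alignments) are labelled ``other`` rather than force-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignfeatures import AlignedRead, group_span, softclip_fraction, supplementary_count
from .refmodel import ReferenceModel, position_in_itr

LABELS = ("duplex", "fillup", "snapback", "multimer", "other")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the DNA-state rules.

    Defaults implement the published decision rules: duplexes below
    10 % soft-clipping; fill-ups/snapbacks in the 40–60 % clipping band
    with exactly one supplementary alignment; multimers at >=75 %
    clipping with more than three supplementary alignments; full-length
    reads start/stop within 50 bp of the genome ends at twice the
    genome length +-150 bp.
    """

    duplex_max_clip: float = 0.10
    fillup_clip_low: float = 0.40
    fillup_clip_high: float = 0.60
    fillup_supp_required: int = 1
    multimer_min_clip: float = 0.75
    multimer_min_supp: int = 4
    full_length_end_tol: int = 50
    full_length_len_tol: int = 150
    itr_axis_tol: int = 100

    def __post_init__(self) -> None:
        if not (
            0
            <= self.duplex_max_clip
            < self.fillup_clip_low
            < self.fillup_clip_high
            < self.multimer_min_clip
            <= 1
        ):
            raise ValueError(
                "thresholds must satisfy 0 <= duplex_max_clip < fillup_clip_low "
                "< fillup_clip_high < multimer_min_clip <= 1"
            )


@dataclass(frozen=True)
class StateCall:
    """Per-read state call with the features that produced it."""

    read_id: str
    label: str
    clip_fraction: float
    n_supp: int
    itr_at_axis: bool | None
    full_length: bool


def fold_point_candidates(read: AlignedRead) -> list[int]:
    """Reference coordinates adjacent to the query midpoint.

    A fold-back read is a palindrome; its fold point sits at the query
    midpoint.  For the primary alignment and every supplementary
    alignment on the same reference, the segment's *inner* end — the
    reference coordinate of the query end facing the midpoint — is a
    candidate for where the molecule folded.
    """
    mid = read.read_length / 2
    segments: list[tuple[tuple[int, int], int, int, str]] = [
        (read.query_interval(), read.ref_start, read.ref_end, read.strand)
    ]
    for sa in read.supplementary:
        if sa.ref_name == read.ref_name:
            segments.append(
                (sa.query_interval(read.read_length), sa.ref_start, sa.ref_end, sa.strand)
            )
    candidates = []
    for (qs, qe), r0, r1, strand in segments:
        first_half = (qs + qe) / 2 < mid
        if first_half:
            # inner query end is qe
            candidates.append(r1 if strand == "+" else r0)
        else:
            candidates.append(r0 if strand == "+" else r1)
    return candidates


def itr_at_symmetry_axis(
    read: AlignedRead, model: ReferenceModel, cfg: ClassifierConfig | None = None
) -> bool:
    """Whether the read's fold point projects into an ITR (± tolerance).

    Returns False for reads without a supplementary alignment on the
    vector reference — a read that did not fold has no symmetry axis.
    """
    cfg = cfg or ClassifierConfig()
    if not any(sa.ref_name == read.ref_name for sa in read.supplementary):
        return False
    return any(
        position_in_itr(model, pos, cfg.itr_axis_tol)
        for pos in fold_point_candidates(read)
    )


class DnaStateClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based DNA-state classifier over per-read alignment features.

    A thin sklearn-style estimator: the thresholds are constructor
    parameters (see :class:`ClassifierConfig` for their meaning), and
    :meth:`predict` maps a feature matrix with columns
    ``(clip_fraction, n_supp, itr_at_axis)`` to state labels.  Rules are
    evaluated in a fixed order (duplex, multimer, fill-up/snapback,
    other); with the default thresholds the rule regions are disjoint,
    so the order is inert.

    There is nothing to estimate from data — :meth:`fit` only validates
    input and records ``classes_`` — but the estimator contract lets the
    classifier slot into sklearn pipelines and model-selection tooling.
    """

    def __init__(
        self,
        duplex_max_clip: float = 0.10,
        fillup_clip_low: float = 0.40,
        fillup_clip_high: float = 0.60,
        fillup_supp_required: int = 1,
        multimer_min_clip: float = 0.75,
        multimer_min_supp: int = 4,
        itr_axis_tol: int = 100,
    ) -> None:
        self.duplex_max_clip = duplex_max_clip
        self.fillup_clip_low = fillup_clip_low
        self.fillup_clip_high = fillup_clip_high
        self.fillup_supp_required = fillup_supp_required
        self.multimer_min_clip = multimer_min_clip
        self.multimer_min_supp = multimer_min_supp
        self.itr_axis_tol = itr_axis_tol

    def _validate_thresholds(self) -> None:
        if not (
            0
            <= self.duplex_max_clip
            < self.fillup_clip_low
            < self.fillup_clip_high
            < self.multimer_min_clip
            <= 1
        ):
            raise ValueError("inconsistent clip thresholds")

    @classmethod
    def from_config(cls, cfg: ClassifierConfig) -> "DnaStateClassifier":
        return cls(
            duplex_max_clip=cfg.duplex_max_clip,
            fillup_clip_low=cfg.fillup_clip_low,
            fillup_clip_high=cfg.fillup_clip_high,
            fillup_supp_required=cfg.fillup_supp_required,
            multimer_min_clip=cfg.multimer_min_clip,
            multimer_min_supp=cfg.multimer_min_supp,
            itr_axis_tol=cfg.itr_axis_tol,
        )

    @staticmethod
    def _as_features(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            clip = X["clip_fraction"].to_numpy(dtype=float)
            n_supp = X["n_supp"].to_numpy(dtype=int)
            axis = X["itr_at_axis"].to_numpy(dtype=bool)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(
                    "expected columns (clip_fraction, n_supp, itr_at_axis)"
                )
            clip, n_supp, axis = arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(bool)
        if np.any((clip < 0) | (clip > 1)):
            raise ValueError("clip_fraction must be in [0, 1]")
        return clip, n_supp, axis

    def fit(self, X, y=None) -> "DnaStateClassifier":
        self._validate_thresholds()
        self._as_features(X)
        self.classes_ = np.asarray(LABELS)
        self.n_features_in_ = 3
        return self

    def predict(self, X) -> np.ndarray:
        self._validate_thresholds()
        clip, n_supp, axis = self._as_features(X)
        labels = np.full(clip.shape, "other", dtype=object)
        in_band = (clip >= self.fillup_clip_low) & (clip <= self.fillup_clip_high)
        foldback = in_band & (n_supp == self.fillup_supp_required)
        labels[foldback & ~axis] = "snapback"
        labels[foldback & axis] = "fillup"
        labels[(clip >= self.multimer_min_clip) & (n_supp >= self.multimer_min_supp)] = (
            "multimer"
        )
        labels[clip < self.duplex_max_clip] = "duplex"
        return labels.astype(str)

    def predict_read(self, read: AlignedRead, model: ReferenceModel) -> str:
        cfg = ClassifierConfig(itr_axis_tol=self.itr_axis_tol)
        axis = itr_at_symmetry_axis(read, model, cfg)
        X = pd.DataFrame(
            {
                "clip_fraction": [softclip_fraction(read)],
                "n_supp": [supplementary_count(read)],
                "itr_at_axis": [axis],
            }
        )
        return str(self.predict(X)[0])


def classify_state(
    read: AlignedRead, model: ReferenceModel, cfg: ClassifierConfig | None = None
) -> StateCall:
    """Classify one vector-mapped read into its DNA state.

    Raises ``ValueError`` for reads whose primary alignment is not on a
    vector-category reference; the caller is expected to filter.
    """
    cfg = cfg or ClassifierConfig()
    if model.category_of(read.ref_name) != "vector":
        raise ValueError(
            f"read {read.read_id} maps to non-vector reference {read.ref_name!r}"
        )
    clip = softclip_fraction(read)
    n_supp = supplementary_count(read)
    axis = itr_at_symmetry_axis(read, model, cfg) if n_supp else None
    clf = DnaStateClassifier.from_config(cfg)
    label = clf.predict(
        pd.DataFrame(
            {"clip_fraction": [clip], "n_supp": [n_supp], "itr_at_axis": [bool(axis)]}
        )
    )[0]
    return StateCall(
        read_id=read.read_id,
        label=label,
        clip_fraction=clip,
        n_supp=n_supp,
        itr_at_axis=axis,
        full_length=is_full_length(read, model, cfg),
    )


def is_full_length(
    read: AlignedRead, model: ReferenceModel, cfg: ClassifierConfig | None = None
) -> bool:
    """Full-length rule: both ends near the genome boundaries, read
    length twice the genome length.

    True iff the span of primary plus same-reference supplementary
    alignments starts within ``full_length_end_tol`` of the expected
    genome start, ends within the same tolerance of the expected stop,
    and the read length is within ``full_length_len_tol`` of 2 L.  The
    doubling reflects the library chemistry: a sequenced full-length
    genome is a fill-up, i.e. genome plus its complementary copy.
    """
    cfg = cfg or ClassifierConfig()
    left, right = group_span(read)
    L = model.genome_length
    return (
        abs(left - model.genome_start) <= cfg.full_length_end_tol
        and abs(right - model.genome_end) <= cfg.full_length_end_tol
        and 2 * L - cfg.full_length_len_tol
        <= read.read_length
        <= 2 * L + cfg.full_length_len_tol
    )


def classify_reads(
    reads: Iterable[AlignedRead],
    model: ReferenceModel,
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify every vector-mapped read; returns the per-read call table.

    Non-vector reads are silently excluded (they feed the contaminant
    summary instead).
    """
    cfg = cfg or ClassifierConfig()
    rows = []
    for read in reads:
        if model.category_of(read.ref_name) != "vector":
            continue
        rows.append(
            {
                "read_id": read.read_id,
                "clip_fraction": softclip_fraction(read),
                "n_supp": supplementary_count(read),
                "itr_at_axis": itr_at_symmetry_axis(read, model, cfg),
                "full_length": is_full_length(read, model, cfg),
                "read_length": read.read_length,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["read_id", "clip_fraction", "n_supp", "itr_at_axis", "full_length", "read_length"],
    )
    if df.empty:
        df["label"] = pd.Series(dtype=str)
    else:
        df["label"] = DnaStateClassifier.from_config(cfg).predict(df)
    return df[
        ["read_id", "label", "clip_fraction", "n_supp", "itr_at_axis", "full_length", "read_length"]
    ]


def summarize(calls: pd.DataFrame, bin_width: int = 100) -> dict:
    """Sample-level summary: % full-length, state composition, and
    read-length histogram data per state.

    ``calls`` is the table from :func:`classify_reads`.  The full-length
    percentage divides full-length reads by *all* vector reads.
    """
    if calls.empty:
        raise ValueError("no vector reads to summarize")
    n = len(calls)
    full_length_pct = 100.0 * calls["full_length"].sum() / n
    composition = (
        calls["label"].value_counts().reindex(list(LABELS), fill_value=0) / n * 100.0
    )
    bins = (calls["read_length"] // bin_width * bin_width).astype(int)
    hist = (
        pd.DataFrame({"length_bin": bins, "state": calls["label"]})
        .groupby(["length_bin", "state"], observed=True)
        .size()
        .reset_index(name="count")
        .sort_values(["length_bin", "state"])
        .reset_index(drop=True)
    )
    return {
        "n_reads": int(n),
        "full_length_pct": float(full_length_pct),
        "state_composition_pct": {k: float(v) for k, v in composition.items()},
        "length_histogram": hist,
    }


def contaminant_base_fractions(
    reads: Iterable[AlignedRead], model: ReferenceModel
) -> pd.Series:
    """Percentage of aligned bases per reference category.

    Each read's aligned bases are attributed to the category of its
    primary reference.  Percentages sum to 100.
    """
    totals: dict[str, int] = {}
    for read in reads:
        cat = model.category_of(read.ref_name)
        totals[cat] = totals.get(cat, 0) + read.aligned_bases
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("zero aligned bases")
    cats = [c for c in ("vector", "human", "ecoli", "repcaphelper", "other")]
    return pd.Series(
        {c: 100.0 * totals.get(c, 0) / grand for c in cats}, name="pct_aligned_bases"
    )
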