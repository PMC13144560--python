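"""Yield, fluorometric-correction and mass-photometry models.

Three small quantitative models around the sequencing workflow:

1. **Expected ssDNA yield.**  From the vector-genome count and genome
   length, the expected single-stranded DNA mass in grams is

       m = n_vg / N_A * (L * 307.97 + 18.02)

   with N_A Avogadro's number, 307.97 g/mol the average nucleotide
   mass, and 18.02 g/mol one water per molecule.  The ratio of measured
   to expected mass flags extraction methods that over- or
   under-recover.

2. **dsDNA interference in fluorometric ssDNA quantitation.**  The
   ssDNA assay dye also binds dsDNA; a spiking experiment mixing known
   ssDNA and dsDNA amounts shows the readout follows
   ``measured = ss + f * ds``.  :class:`DsDnaInterferenceModel` fits
   the interference factor ``f`` by origin-constrained least squares on
   the residuals ``measured - ss``; on the published spiking table the
   factor comes out at 4.5.

3. **Mass-photometry boundary transfer.**  Capsid-population boundaries
   measured in kDa convert to payload length at 0.33 kDa per
   nucleotide above the empty-capsid mass, then doubled because
   double-strand synthesis doubled each molecule before sequencing.
   Empty-fraction counts are excluded and partial/full renormalised to
   100 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

AVOGADRO = 6.022e23
#: average mass of one nucleotide in ssDNA, g/mol
G_PER_MOL_NT = 307.97
#: one water molecule per ssDNA strand, g/mol
G_PER_MOL_WATER = 18.02
#: mass-photometry conversion, kDa per nucleotide of packaged ssDNA
KDA_PER_NT = 0.33
#: double-strand synthesis doubles molecule length before sequencing
DS_SYNTHESIS_SCALE = 2


def expected_ssdna_mass(vg_count: float, length_nt: float) -> float:
    """Expected ssDNA mass in grams for ``vg_count`` genomes of
    ``length_nt`` nucleotides."""
    if vg_count <= 0 or length_nt <= 0:
        raise ValueError("vg_count and length_nt must be positive")
    return vg_count / AVOGADRO * (length_nt * G_PER_MOL_NT + G_PER_MOL_WATER)


def yield_ratio(measured_conc_ng_ul: float, volume_ul: float, expected_mass_g: float) -> float:
    """Obtained/expected ssDNA ratio.

    ``measured_conc_ng_ul * volume_ul`` gives the obtained mass in ng,
    converted to grams before dividing by the expected mass.
    """
    if expected_mass_g <= 0:
        raise ValueError("expected mass must be positive")
    obtained_g = measured_conc_ng_ul * volume_ul * 1e-9
    return obtained_g / expected_mass_g


@dataclass(frozen=True)
class SpikingTable:
    """Rows of a dsDNA/ssDNA spiking experiment.

    Each row mixes a known dsDNA and ssDNA concentration (ng/ul) and
    records replicate fluorometric readouts.
    """

    ds_conc: tuple[float, ...]
    ss_conc: tuple[float, ...]
    measurements: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if not (len(self.ds_conc) == len(self.ss_conc) == len(self.measurements)):
            raise ValueError("columns must have equal length")
        if any(d < 0 for d in self.ds_conc) or any(s < 0 for s in self.ss_conc):
            raise ValueError("concentrations must be >= 0")

    @property
    def row_means(self) -> np.ndarray:
        """Replicate average per row (the table's Average row)."""
        return np.array([float(np.mean(m)) for m in self.measurements])

    def to_frame(self) -> pd.DataFrame:
        n_rep = max(len(m) for m in self.measurements)
        data = {"ds_ng_ul": self.ds_conc, "ss_ng_ul": self.ss_conc}
        for i in range(n_rep):
            data[f"m{i + 1}"] = [m[i] if i < len(m) else np.nan for m in self.measurements]
        return pd.DataFrame(data)


def load_spiking_table(csv_path: str | Path) -> SpikingTable:
    """Read a spiking table from CSV (columns ds_ng_ul, ss_ng_ul, m1, m2, ...)."""
    df = pd.read_csv(csv_path)
    meas_cols = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
    if not meas_cols:
        raise ValueError("no measurement columns (m1, m2, ...) found")
    return SpikingTable(
        ds_conc=tuple(df["ds_ng_ul"].astype(float)),
        ss_conc=tuple(df["ss_ng_ul"].astype(float)),
        measurements=tuple(
            tuple(row[c] for c in meas_cols if pd.notna(row[c])) for _, row in df.iterrows()
        ),
    )


def published_spiking_table() -> SpikingTable:
    """The packaged dsDNA/ssDNA spiking experiment shipped with aavqc."""
    with resources.as_file(
        resources.files("aavqc").joinpath("data/qubit_ssdna_spiking.csv")
    ) as path:
        return load_spiking_table(path)


class DsDnaInterferenceModel(RegressorMixin, BaseEstimator):
    """Origin-constrained least-squares fit of the dsDNA interference
    factor in a fluorometric ssDNA assay.

    The model is ``measured = ss_coef * ss + f * ds``; by default the
    ssDNA contribution is pinned at 1:1 (``fit_ss_coef=False``) and only
    the interference factor ``f`` is estimated from the residuals
    ``r = mean(measurements) - ss``:

        f = sum(ds * r) / sum(ds^2)

    Parameters
    ----------
    fit_ss_coef
        Also estimate the ssDNA coefficient (two-parameter
        least squares through the origin) instead of fixing it at 1.
    method
        ``"ols"`` (default, uses all rows) or ``"ratio"`` (mean of the
        per-row ratios r/ds over rows with ds > 0).

    Attributes
    ----------
    factor_ : float
        Fitted dsDNA interference factor.
    ss_coef_ : float
        ssDNA coefficient (1.0 unless ``fit_ss_coef``).
    residuals_ : ndarray
        Per-row fit residuals on the replicate means.
    """

    def __init__(self, fit_ss_coef: bool = False, method: str = "ols") -> None:
        self.fit_ss_coef = fit_ss_coef
        self.method = method

    def fit(self, X, y=None) -> "DsDnaInterferenceModel":
        """Fit from a :class:`SpikingTable`, or from ``X = [[ds, ss]]``
        with ``y`` the measured concentrations."""
        if isinstance(X, SpikingTable):
            ds = np.asarray(X.ds_conc, dtype=float)
            ss = np.asarray(X.ss_conc, dtype=float)
            meas = X.row_means
        else:
            arr = np.asarray(X, dtype=float)
            ds, ss = arr[:, 0], arr[:, 1]
            meas = np.asarray(y, dtype=float)
        if np.count_nonzero(ds) == 0:
            raise ValueError("all dsDNA concentrations are zero; factor unidentifiable")
        if len(np.unique(ds)) < 2:
            # a single spiked level still identifies f but warn: no lack-of-fit check
            warnings.warn("only one distinct dsDNA level; fit is a single ratio")
        if self.method == "ratio":
            mask = ds > 0
            self.ss_coef_ = 1.0
            self.factor_ = float(np.mean((meas[mask] - ss[mask]) / ds[mask]))
        elif self.fit_ss_coef:
            A = np.column_stack([ds, ss])
            coef, *_ = np.linalg.lstsq(A, meas, rcond=None)
            self.factor_, self.ss_coef_ = float(coef[0]), float(coef[1])
        else:
            r = meas - ss
            self.ss_coef_ = 1.0
            self.factor_ = float(np.sum(ds * r) / np.sum(ds * ds))
        self.residuals_ = meas - self.predict(np.column_stack([ds, ss]))
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted readout for ``X = [[ds, ss]]``."""
        arr = np.asarray(X, dtype=float)
        return self.ss_coef_ * arr[:, 1] + self.factor_ * arr[:, 0]


def fit_dsdna_factor(table: SpikingTable, method: str = "ols") -> float:
    """Fitted dsDNA interference factor for a spiking table."""
    return DsDnaInterferenceModel(method=method).fit(table).factor_


def corrected_ssdna(measured: float, ds_est: float, f: float) -> float:
    """Subtract the estimated dsDNA contribution from a readout (ng/ul).

    Negative corrected values are floored at 0 with a warning — they
    indicate the dsDNA estimate (or the factor) overshoots.
    """
    if f <= 0:
        raise ValueError("interference factor must be positive")
    if measured < 0:
        raise ValueError("measured concentration must be >= 0")
    value = measured - f * ds_est
    if value < 0:
        warnings.warn(
            f"corrected ssDNA {value:.3g} ng/ul below zero; floored at 0"
        )
        return 0.0
    return value


@dataclass(frozen=True)
class MassPhotometryBoundaries:
    """Capsid-fraction boundaries from a mass-photometry run.

    ``borders`` are the kDa values delimiting the empty / partial /
    full populations; ``mass_empty`` is the empty-capsid mass.
    """

    mass_empty: float
    borders: tuple[float, ...]
    kda_per_nt: float = KDA_PER_NT
    ngs_scale_factor: int = DS_SYNTHESIS_SCALE

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.borders, self.borders[1:])):
            raise ValueError("borders must be strictly increasing")
        if self.borders and self.mass_empty > self.borders[0]:
            raise ValueError("mass_empty must not exceed the first border")


def mass_to_ssdna_length(
    mass_kda: float, boundaries: MassPhotometryBoundaries
) -> tuple[float, float]:
    """Convert a capsid mass to packaged ssDNA length.

    Returns ``(nucleotides, ngs_scale_bp)`` where the second value is
    the length on the sequencing axis — doubled, because double-strand
    synthesis doubles each molecule before library preparation.
    """
    if mass_kda < boundaries.mass_empty:
        raise ValueError("mass below the empty-capsid mass")
    nt = (mass_kda - boundaries.mass_empty) / boundaries.kda_per_nt
    return nt, boundaries.ngs_scale_factor * nt


def normalize_partial_full(counts: dict[str, float]) -> dict[str, float]:
    """Renormalise partial/full counts to percentages summing to 100.

    Any ``empty`` entry is dropped first: the empty fraction cannot be
    seen by sequencing, so it is excluded on both axes before
    comparison.
    """
    partial = float(counts.get("partial", 0.0))
    full = float(counts.get("full", 0.0))
    total = partial + full
    if total <= 0:
        raise ValueError("partial + full counts must be positive")
    return {"partial": 100.0 * partial / total, "full": 100.0 * full / total}
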