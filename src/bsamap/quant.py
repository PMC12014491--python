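"""Closed-form quantifications: ΔΔCt, background-corrected integrated
density, per-replicate t₀ normalization, and exponential half-life fitting.

ΔΔCt relative quantification
    RQ = 2^−[(Ct_target − Ct_ref)_sample − mean ΔCt over calibrator samples],
    with replicate Ct values averaged before any differencing.

Background-corrected integrated density (image densitometry)
    corrected = IntDen_sample − IntDen_background × Area_sample / Area_background.

Half-life
    Ordinary least squares of log₂(signal) on time; τ = −1/slope. A
    non-negative slope is reported as non-decaying (infinite half-life).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    calibrator_samples: list[str],
) -> pd.Series:
    """Relative quantity (2^−ΔΔCt) per sample.

    ``ct_table`` has columns sample_id, gene_id, ct (one row per
    replicate). Replicates are averaged per (sample, gene) first; the
    calibrator ΔCt is the mean ΔCt over ``calibrator_samples``.
    """
    if not calibrator_samples:
        raise DataError("calibrator sample list is empty")
    means = ct_table.groupby(["sample_id", "gene_id"])["ct"].mean().unstack()
    for gene in (target_gene, ref_gene):
        if gene not in means.columns:
            raise DataError(f"no Ct values for gene {gene!r}")
    for col in (target_gene, ref_gene):
        bad = means.index[means[col].isna()]
        if len(bad):
            raise DataError(f"sample {bad[0]!r} lacks Ct for gene {col!r}")
    missing = [s for s in calibrator_samples if s not in means.index]
    if missing:
        raise DataError(f"calibrator sample {missing[0]!r} not in table")
    dct = means[target_gene] - means[ref_gene]
    ddct_values = dct - dct.loc[calibrator_samples].mean()
    rq = 2.0 ** (-ddct_values)
    rq.name = "relative_quantity"
    return rq


@dataclass(frozen=True)
class FluorMeasurement:
    """Integrated densities and areas for a sample region and its background."""

    intden_sample: float
    area_sample: float
    intden_background: float
    area_background: float

    def validate(self) -> None:
        if self.area_sample <= 0 or self.area_background <= 0:
            raise DataError("areas must be positive")
        if self.intden_sample < 0 or self.intden_background < 0:
            raise DataError("integrated densities must be non-negative")


def corrected_intden(m: FluorMeasurement) -> float:
    """Background-corrected integrated density (area-scaled subtraction)."""
    m.validate()
    return m.intden_sample - m.intden_background * m.area_sample / m.area_background


def normalize_t0(
    series: pd.DataFrame,
    time_col: str = "time_h",
    value_col: str = "signal",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Divide every value by its replicate's mean signal at t = 0."""
    out = series.copy()
    for rep, group in out.groupby(replicate_col):
        at0 = group.loc[group[time_col] == 0, value_col]
        if at0.empty:
            raise DataError(f"replicate {rep!r} has no t=0 observation")
        out.loc[group.index, value_col] = group[value_col] / at0.mean()
    return out


@dataclass(frozen=True)
class HalfLifeFit:
    """Log-linear decay fit: S(t) ≈ s0 · 2^(−t/half_life)."""

    half_life: float  # hours; math.inf when non-decaying
    s0: float
    slope: float  # log2 units per hour
    n: int

    @property
    def is_decaying(self) -> bool:
        return math.isfinite(self.half_life)

    def fraction_remaining(self, t: float) -> float:
        """Model-predicted fraction of the initial signal left at time t."""
        return 2.0 ** (self.slope * t)

    def summary(self) -> str:
        hl = f"{self.half_life:.3g} h" if self.is_decaying else "non-decaying"
        return (
            f"half-life: {hl} (log2-linear fit over {self.n} points, "
            f"slope {self.slope:.4g} /h, s0 {self.s0:.4g})"
        )


def fit_half_life(
    timepoints: "np.ndarray | list[float]",
    signals: "np.ndarray | list[float]",
) -> HalfLifeFit:
    """Least-squares fit of log₂(signal) against time.

    Exact on noiseless exponentials; a non-negative fitted slope is
    reported as non-decaying with ``half_life = inf``.
    """
    t = np.asarray(timepoints, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.size < 3:
        raise DataError("need at least 3 points to fit a half-life")
    if np.any(s <= 0):
        raise DataError("signals must be positive for log fitting")
    slope, intercept = np.polyfit(t, np.log2(s), 1)
    half_life = math.inf if slope >= 0 else -1.0 / slope
    return HalfLifeFit(
        half_life=half_life, s0=float(2.0 ** intercept), slope=float(slope), n=t.size
    )
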