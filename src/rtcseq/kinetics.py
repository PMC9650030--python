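"""Translation elongation speed and fidelity from reporter assays.

Elongation speed comes from an induction time course of a long reporter
protein: no full-length product exists until one ribosome has traversed
the ORF, after which accumulation grows quadratically, so the square
root of the signal is linear in time and its X-intercept is the time to
translate the reporter once (a Schleif plot).  Speed is reporter length
divided by that translation time.

Fidelity is the normalized miscoding ratio: activity of an error
reporter (frameshift or premature stop, which yields product only on a
translational error) over activity of the wild-type reporter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import KineticsSeries

#: Length of the FusA-LacZα fusion reporter, in amino acids.
DEFAULT_PROTEIN_LEN = 774


def speed_from_time(translation_time: float, protein_len: int = DEFAULT_PROTEIN_LEN) -> float:
    """Elongation speed (aa/s) = reporter length / translation time."""
    if translation_time <= 0:
        raise ValueError(f"translation_time must be > 0, got {translation_time}")
    return protein_len / translation_time


@dataclass
class SpeedEstimate:
    """Schleif-plot fit: sqrt(signal) = slope * t + intercept."""

    translation_time: float  # s; the X-intercept, -intercept/slope
    speed: float  # aa/s
    slope: float
    intercept: float
    r2: float
    n_points_used: int
    protein_len: int


def schleif_fit(
    series: KineticsSeries,
    protein_len: int = DEFAULT_PROTEIN_LEN,
    noise_floor: float | None = None,
) -> SpeedEstimate:
    """Estimate translation time and elongation speed from a time course.

    Background is subtracted and the signal floored at 0 before the
    square root.  Points entering the ordinary-least-squares line are
    those with sqrt(signal) strictly above a noise floor, so pre-onset
    zeros never enter.  When ``noise_floor`` is given it is used as-is
    (sqrt-signal units).  By default the linear region is found
    adaptively: an initial fit over points whose signal exceeds twice
    the pre-onset baseline scatter (samples below 5% of the maximum) is
    refined by keeping only points whose fitted sqrt-signal exceeds 3x
    the residual scatter — the region where the Schleif plot is linear
    above the noise.  For noise-free data every positive sample is used
    and the fit is exact.

    The translation time is the X-intercept -intercept/slope of the fit;
    it is scale-free, so multiplying the signal by any positive constant
    leaves the estimate unchanged.
    """
    signal = np.maximum(series.signal - series.background, 0.0)
    root = np.sqrt(signal)
    if not np.any(root > 0):
        raise ValueError("no productive synthesis: signal never rises above background")

    def _ols(mask):
        if mask.sum() < 2:
            raise ValueError(f"only {int(mask.sum())} usable points; need at least 2")
        return sm.OLS(root[mask], sm.add_constant(series.time[mask])).fit()

    if noise_floor is not None:
        usable = root > max(noise_floor, 0.0)
        fit = _ols(usable)
    else:
        baseline = signal[signal <= 0.05 * signal.max()]
        usable = signal > 2.0 * float(baseline.std())
        fit = _ols(usable)
        for _ in range(5):
            resid_sd = float(np.sqrt(fit.mse_resid))
            predicted = fit.params[0] + fit.params[1] * series.time
            refined = (predicted > 3.0 * resid_sd) & (root > 0)
            if refined.sum() < 3 or np.array_equal(refined, usable):
                break
            usable = refined
            fit = _ols(usable)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    if slope <= 0:
        raise ValueError("no productive synthesis: non-positive Schleif slope")
    translation_time = -intercept / slope
    if translation_time <= 0:
        raise ValueError(
            f"fitted X-intercept {translation_time:.3g} s is not positive; "
            "the series may start mid-accumulation"
        )
    return SpeedEstimate(
        translation_time=translation_time,
        speed=speed_from_time(translation_time, protein_len),
        slope=slope,
        intercept=intercept,
        r2=float(fit.rsquared) if usable.sum() > 2 else 1.0,
        n_points_used=int(usable.sum()),
        protein_len=protein_len,
    )


def percent_speed_reduction(v_reference: float, v_mutant: float) -> float:
    """Percent change 100 * (1 - v_mutant / v_reference)."""
    if v_reference <= 0:
        raise ValueError("reference speed must be > 0")
    return 100.0 * (1.0 - v_mutant / v_reference)


# ---------------------------------------------------------------------------
# fidelity

@dataclass(frozen=True)
class FidelityResult:
    reporter: str
    normalized_miscoding: float
    miscoding_sd: float
    mu_reporter: float
    mu_wt: float
    n_replicates: int


def normalized_miscoding(mu_reporter: float, mu_wt: float) -> float:
    """Error-reporter activity over wild-type-reporter activity."""
    if mu_wt <= 0:
        raise ValueError(f"mu_wt must be > 0, got {mu_wt}")
    if mu_reporter < 0:
        raise ValueError(f"mu_reporter must be >= 0, got {mu_reporter}")
    return mu_reporter / mu_wt


def summarize_fidelity(table: pd.DataFrame) -> list[FidelityResult]:
    """Average a replicate Miller-unit table into per-reporter
    normalized-miscoding ratios.

    The table needs columns ``reporter`` (with a ``wildtype`` level),
    ``replicate`` and ``miller_units``; each error-reporter replicate is
    normalized by the wild-type replicate mean, and the per-reporter
    mean ratio and its standard deviation are reported.
    """
    required = {"reporter", "replicate", "miller_units"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wt = table.loc[table["reporter"] == "wildtype", "miller_units"]
    if wt.empty:
        raise ValueError("table has no wildtype reporter rows")
    mu_wt = float(wt.mean())
    if mu_wt <= 0:
        raise ValueError("wild-type mean Miller units must be > 0")
    out = []
    for reporter, group in table[table["reporter"] != "wildtype"].groupby("reporter"):
        ratios = group["miller_units"].to_numpy(dtype=float) / mu_wt
        out.append(
            FidelityResult(
                reporter=str(reporter),
                normalized_miscoding=float(ratios.mean()),
                miscoding_sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                mu_reporter=float(group["miller_units"].mean()),
                mu_wt=mu_wt,
                n_replicates=len(ratios),
            )
        )
    return out


# ---------------------------------------------------------------------------
# model / results facade

class SchleifModel:
    """Elongation-speed estimation from one induction time course."""

    def __init__(
        self,
        time: Sequence[float] | np.ndarray,
        signal: Sequence[float] | np.ndarray,
        protein_len: int = DEFAULT_PROTEIN_LEN,
        background: float = 0.0,
    ):
        self.series = KineticsSeries(np.asarray(time, float), np.asarray(signal, float), background)
        self.protein_len = protein_len

    @classmethod
    def from_series(cls, series: KineticsSeries, protein_len: int = DEFAULT_PROTEIN_LEN):
        return cls(series.time, series.signal, protein_len, series.background)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        protein_len: int = DEFAULT_PROTEIN_LEN,
        background: float = 0.0,
    ):
        return cls(table["time_s"], table["signal"], protein_len, background)

    def fit(self, noise_floor: float | None = None) -> "SchleifResults":
        est = schleif_fit(self.series, self.protein_len, noise_floor=noise_floor)
        return SchleifResults(self, est)


@dataclass
class SchleifResults:
    model: SchleifModel
    estimate: SpeedEstimate

    @property
    def speed(self) -> float:
        return self.estimate.speed

    @property
    def translation_time(self) -> float:
        return self.estimate.translation_time

    def plot(self, ax=None):
        """Schleif plot: sqrt(signal) vs time with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        root = np.sqrt(np.maximum(s.signal - s.background, 0.0))
        ax.plot(s.time, root, "o", ms=4)
        e = self.estimate
        tt = np.array([e.translation_time, s.time.max()])
        ax.plot(tt, e.slope * tt + e.intercept, "-", color="red", lw=1)
        ax.set_xlabel("induction time (s)")
        ax.set_ylabel("sqrt(reporter signal)")
        return ax

    def summary(self) -> str:
        e = self.estimate
        return "\n".join(
            [
                "Schleif-plot elongation-speed estimate",
                "=" * 38,
                f"reporter length:     {e.protein_len} aa",
                f"points fitted:       {e.n_points_used}",
                f"slope:               {e.slope:.6g} sqrt(AU)/s",
                f"X-intercept:         {e.translation_time:.4g} s (translation time)",
                f"elongation speed:    {e.speed:.4g} aa/s",
                f"R^2:                 {e.r2:.6f}",
            ]
        )
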