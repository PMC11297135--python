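"""Outlier filtering, harmonic seasonal detrending and linear trends.

The seasonal model is the oscillatory function

    y(t) = A * sin(omega * t + phi) + B * t + C

with the angular frequency fixed at the annual cycle,
``omega = 2*pi`` rad yr^-1 (t in decimal years).  Because the model is
linear in ``a = A*cos(phi)`` and ``b = A*sin(phi)`` when written as
``a*sin(omega t) + b*cos(omega t) + B*t + C``, it is solved by linear
least squares; no non-convex frequency search is needed.  After the
fitted seasonal component is subtracted, a standard linear regression
of the deseasonalized series on time gives the reported trend B, its
t-distribution confidence interval, r-squared and two-sided p-value.
Trends with p > 0.01 are flagged as not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

OMEGA_ANNUAL = 2.0 * math.pi  # rad / yr

SIGNIFICANCE_P = 0.01

MIN_POINTS = 8
MIN_SPAN_YEARS = 2.0

#: a series whose total variation is below this, relative to its mean
#: magnitude, is treated as constant: slope inference on it is vacuous
#: (there is no noise against which to test), so the p-value is
#: reported as 1.  The floor sits far below measurement resolution for
#: every variable handled here (pH electrodes resolve ~2e-4 relative,
#: TA titrations ~1e-3), while solver/model wiggle on degenerate
#: constant inputs stays beneath it.
FLAT_RTOL = 1e-5


class TrendFitError(ValueError):
    pass


@dataclass
class TimeSeries:
    """One stratum's series of one variable on a decimal-year axis."""
    stratum: str
    variable: str      # ph | h | ta | nta
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in time series")

    def __len__(self):
        return len(self.t)


@dataclass
class SeasonalTrendFit:
    """Coefficients of the oscillatory model plus trend inference."""
    A: float
    omega: float
    phi: float
    B: float
    C: float
    ci_B: tuple
    r2: float
    p_value: float
    n_used: int
    significant: bool
    confidence: float = 0.95
    stderr_B: float = float("nan")

    def to_dict(self):
        return {"A": self.A, "omega": self.omega, "phi": self.phi,
                "B": self.B, "ci_lo": self.ci_B[0], "ci_hi": self.ci_B[1],
                "C": self.C, "r2": self.r2, "p_value": self.p_value,
                "n_used": self.n_used, "significant": self.significant,
                "stderr_B": self.stderr_B}


def remove_outliers(series: TimeSeries, z_max: float = 3.0):
    """Drop points more than ``z_max`` sample standard deviations from
    the series mean, in a single pass (no re-iteration).

    A constant series (sd = 0) is returned unchanged.  Returns the
    filtered series and the number of points removed.
    """
    if z_max <= 0:
        raise ValueError("z_max must be > 0")
    y = series.y
    sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
    if sd == 0 or not np.isfinite(z_max):
        keep = np.ones(len(y), bool)
    else:
        keep = np.abs(y - y.mean()) / sd <= z_max
    filtered = TimeSeries(series.stratum, series.variable,
                          series.t[keep], y[keep])
    return filtered, int((~keep).sum())


def fit_seasonal_trend(series: TimeSeries, confidence: float = 0.95,
                       omega: float = OMEGA_ANNUAL) -> SeasonalTrendFit:
    """Fit the oscillatory model and report the second-stage trend.

    Stage 1 solves ``y = a sin(omega t) + b cos(omega t) + B t + C`` by
    least squares on a mean-centered time axis (for conditioning).
    Stage 2 subtracts the fitted seasonal component and regresses the
    deseasonalized series on t, yielding the reported B, its
    ``confidence``-level CI (t distribution, n-2 df), r-squared and
    two-sided p-value for slope != 0.
    """
    t, y = series.t, series.y
    n = len(t)
    if n < MIN_POINTS:
        raise TrendFitError(f"need >= {MIN_POINTS} points, got {n}")
    span = t[-1] - t[0]
    if span < MIN_SPAN_YEARS:
        raise TrendFitError(f"need a span of >= {MIN_SPAN_YEARS} yr, got {span:.3g}")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")

    tbar = t.mean()
    tau = t - tbar
    design = np.column_stack([np.sin(omega * tau), np.cos(omega * tau),
                              tau, np.ones(n)])
    rank = np.linalg.matrix_rank(design)
    if rank < 4:
        raise TrendFitError("rank-deficient seasonal design (all points at the same phase?)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    A = math.hypot(a, b)
    # a sin(w tau) + b cos(w tau) = A sin(w t + phi) with the phase mapped
    # back from the centered axis
    phi = (math.atan2(b, a) - omega * tbar) % (2.0 * math.pi)

    deseason = y - (a * np.sin(omega * tau) + b * np.cos(omega * tau))
    res = stats.linregress(tau, deseason)
    B = float(res.slope)
    C = float(res.intercept) - B * tbar
    se = float(res.stderr)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    ci = (B - tcrit * se, B + tcrit * se)
    p = float(res.pvalue)
    if float(np.std(y)) <= FLAT_RTOL * max(1.0, abs(float(np.mean(y)))):
        p = 1.0  # flat series: no noise against which to test the slope
    return SeasonalTrendFit(
        A=A, omega=omega, phi=phi, B=B, C=C, ci_B=ci,
        r2=float(res.rvalue ** 2), p_value=p, n_used=n,
        significant=bool(p <= SIGNIFICANCE_P), confidence=confidence,
        stderr_B=se,
    )


def trend_table(series_collection, z_max: float = 3.0,
                confidence: float = 0.95) -> pd.DataFrame:
    """Outlier-filter and fit every series; one row per stratum x variable.

    Per-series failures are recorded as flagged rows (``error`` column)
    rather than aborting the table.  Ordering follows the input
    collection, which the pipeline builds station-major, depth-minor.
    """
    rows = []
    for series in series_collection:
        row = {"stratum": series.stratum, "variable": series.variable}
        try:
            filtered, n_removed = remove_outliers(series, z_max=z_max)
            fit = fit_seasonal_trend(filtered, confidence=confidence)
            row.update(fit.to_dict())
            row["n_removed"] = n_removed
            row["error"] = ""
        except (TrendFitError, ValueError) as exc:
            row.update({k: np.nan for k in
                        ("A", "omega", "phi", "B", "ci_lo", "ci_hi", "C",
                         "r2", "p_value", "stderr_B")})
            row.update({"n_used": 0, "n_removed": 0,
                        "significant": False, "error": str(exc)})
        rows.append(row)
    cols = ["stratum", "variable", "B", "ci_lo", "ci_hi", "stderr_B", "r2",
            "p_value", "significant", "A", "omega", "phi", "C", "n_used",
            "n_removed", "error"]
    return pd.DataFrame(rows)[cols]


def format_trend_table(table: pd.DataFrame) -> pd.DataFrame:
    """Compact report layout: trend +/- half-CI with an asterisk marking
    non-significant (p > 0.01) entries."""
    out = table[["stratum", "variable"]].copy()
    half = (table["ci_hi"] - table["ci_lo"]) / 2.0
    star = np.where(table["significant"], "", "*")
    out["trend"] = [
        f"{b:+.4g} ± {h:.2g}{s}" if np.isfinite(b) else "failed"
        for b, h, s in zip(table["B"], half, star)
    ]
    return out
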