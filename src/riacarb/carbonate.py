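"""Deterministic carbonate-system transforms.

Hydrogen-ion concentration from pH, and salinity normalization of
total alkalinity (TA) by either the traditional reference-salinity
ratio or the empirical alkalinity-salinity slope.  Working in [H+]
(nmol kg^-1) rather than pH avoids the non-linearity of the
logarithmic scale when quantifying acidification trends; normalizing
TA to a reference salinity of 35 strips the dilution/evaporation
signal so the underlying biogeochemical trend is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_SALINITY = 35.0

#: guard for the ratio method, which blows up toward fresh water
DEFAULT_S_MIN = 5.0


class TransformError(ValueError):
    pass


def ph_to_h(ph, ph_min: float = 0.0, ph_max: float = 14.0):
    """Total hydrogen-ion concentration in nmol kg^-1: ``h = 10**(9 - pH)``.

    Strictly decreasing in pH; pH 8 maps to 10 nmol kg^-1.  Values
    outside (ph_min, ph_max) raise, which catches unit confusion (e.g.
    being handed [H+] values instead of pH).
    """
    ph = np.asarray(ph, float)
    if not np.all(np.isfinite(ph)):
        raise TransformError("non-finite pH")
    if np.any(ph <= ph_min) or np.any(ph >= ph_max):
        raise TransformError(
            f"pH outside ({ph_min}, {ph_max}); input does not look like pH units")
    out = 10.0 ** (9.0 - ph)
    return float(out) if out.ndim == 0 else out


def h_to_ph(h):
    """Inverse transform, ``ph = 9 - log10(h)`` with h in nmol kg^-1."""
    h = np.asarray(h, float)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise TransformError("[H+] must be positive and finite")
    out = 9.0 - np.log10(h)
    return float(out) if out.ndim == 0 else out


def nta_reference(ta, s, s_min: float = DEFAULT_S_MIN):
    """Traditional ratio normalization ``NTA = TA * 35 / S``.

    Refuses salinities at or below ``s_min``: the ratio method is known
    to over-correct and degenerate toward river mouths, where TA does
    not extrapolate to zero at S = 0.
    """
    ta = np.asarray(ta, float)
    s = np.asarray(s, float)
    if np.any(s <= s_min):
        raise TransformError(
            f"salinity <= {s_min}: the reference-salinity method is unreliable "
            "in nearly fresh water (TA does not vanish at S = 0)")
    out = ta * REFERENCE_SALINITY / s
    return float(out) if out.ndim == 0 else out


@dataclass
class AlphaFit:
    """Fitted TA-vs-salinity slope for one stratum (or pooled 'global')."""
    alpha: float       # umol/kg per salinity unit
    intercept: float   # umol/kg
    r2: float
    n: int
    stratum: str = "global"
    stderr: float = float("nan")

    def to_dict(self):
        return {"stratum": self.stratum, "alpha": self.alpha,
                "intercept": self.intercept, "r2": self.r2, "n": self.n,
                "stderr": self.stderr}


def fit_alpha(ta_values, s_values, stratum: str = "global") -> AlphaFit:
    """Ordinary least-squares slope of TA on salinity."""
    ta = np.asarray(ta_values, float)
    s = np.asarray(s_values, float)
    ok = np.isfinite(ta) & np.isfinite(s)
    ta, s = ta[ok], s[ok]
    if len(ta) < 3:
        raise TransformError(f"need >= 3 paired TA/S values, got {len(ta)}")
    if np.ptp(s) == 0 or np.var(s) == 0:
        raise TransformError("zero salinity variance: alpha fit is degenerate")
    res = stats.linregress(s, ta)
    r2 = float(res.rvalue ** 2)
    if not np.isfinite(r2):
        r2 = 0.0  # constant TA: no variance to explain
    return AlphaFit(alpha=float(res.slope), intercept=float(res.intercept),
                    r2=r2, n=len(ta), stratum=stratum,
                    stderr=float(res.stderr))


def nta_empirical(ta, s, alpha) -> np.ndarray:
    """Empirical normalization ``NTA = TA + alpha * (35 - S)``.

    ``alpha`` may be an :class:`AlphaFit` or a bare slope.  Identity at
    S = 35 and for alpha = 0.
    """
    a = alpha.alpha if isinstance(alpha, AlphaFit) else float(alpha)
    ta = np.asarray(ta, float)
    s = np.asarray(s, float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(s)) and np.isfinite(a)):
        raise TransformError("non-finite inputs to nta_empirical")
    out = ta + a * (REFERENCE_SALINITY - s)
    return float(out) if out.ndim == 0 else out


def alpha_table(table: pd.DataFrame, ta_col: str = "ta_umol_kg",
                s_col: str = "salinity") -> pd.DataFrame:
    """Per-stratum (station x depth) and pooled global alpha fits.

    Returns a tidy frame (stratum, alpha, intercept, r2, n, stderr)
    with the global fit last.
    """
    rows = []
    for (st, dep), grp in table.groupby(["station_id", "depth_m"], sort=True):
        try:
            fit = fit_alpha(grp[ta_col], grp[s_col], stratum=f"{st}@{dep:g}m")
            rows.append(fit.to_dict())
        except TransformError as exc:
            rows.append({"stratum": f"{st}@{dep:g}m", "alpha": np.nan,
                         "intercept": np.nan, "r2": np.nan,
                         "n": len(grp), "stderr": np.nan})
    rows.append(fit_alpha(table[ta_col], table[s_col], stratum="global").to_dict())
    return pd.DataFrame(rows)
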