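"""Synthetic coastal hydrography with planted ground truth.

Generates two tables that emulate the data situation of a long-running
coastal monitoring programme in an upwelling-influenced embayment (a
Galician ría):

* a *training* table of discrete hydrographic samples with measured pH
  and/or total alkalinity (TA), scattered irregularly over four decades
  and over the embayment, as cruise data would be; and
* a *prediction* table of weekly predictor measurements (temperature,
  salinity, nutrients) at a fixed set of stations and depth bins, with
  no carbonate observations — the series the trained proxy models are
  applied to.

Every generated label decomposes exactly into the terms of the
generative model held in :class:`SyntheticWorldSpec`, so downstream
estimators (proxy regressions, alkalinity–salinity slopes, seasonal
detrending, linear trends) have recoverable targets.

Generative model
----------------
A latent "upwelling" driver ``u(t) = sin(2*pi*t + phase) + eps_u(t)``
carries the shared seasonality plus weekly weather variability.  Cold,
nutrient-rich, low-pH water corresponds to high ``u``.  Each variable
loads on ``u`` with its own sign and gain; pH additionally carries a
planted linear acidification trend that varies smoothly with position
and depth, and TA is linear in (true) salinity plus its own trend.
Observation noise is additive, independent and Gaussian per variable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

#: canonical column order of the delimited tables
COLUMNS = [
    "station_id",
    "latitude",
    "longitude",
    "depth_m",
    "date",
    "year_decimal",
    "week",
    "temperature_c",
    "salinity",
    "phosphate_umol_kg",
    "nitrate_umol_kg",
    "silicate_umol_kg",
    "ph",
    "ta_umol_kg",
]

#: columns that must be present and numeric in any table
MANDATORY_NUMERIC = [
    "latitude",
    "longitude",
    "depth_m",
    "year_decimal",
    "week",
    "temperature_c",
    "salinity",
    "phosphate_umol_kg",
    "nitrate_umol_kg",
    "silicate_umol_kg",
]

_DEFAULT_NOISE = {
    "ph": 0.02,           # pH units, electrode-grade
    "ta": 5.0,            # umol/kg
    "temperature": 0.1,   # degC
    "salinity": 0.02,     # CTD-grade practical salinity
    "phosphate": 0.05,    # umol/kg
    "nitrate": 0.3,       # umol/kg
    "silicate": 0.3,      # umol/kg
    "upwelling": 0.5,     # latent driver weather variability (dimensionless)
}


class WorldSpecError(ValueError):
    """Raised when a SyntheticWorldSpec violates its invariants."""


@dataclass
class SyntheticWorldSpec:
    """Complete description of the synthetic world, including all planted
    truths against which recovery is judged.

    Trend and offset fields define smooth spatial fields rather than
    per-stratum lookup tables, so that proxy models can learn them from
    scattered training positions: the planted pH trend at longitude
    ``lon`` (deg E, negative W) and depth ``z`` (m) is::

        ph_trend_base
          + ph_trend_lon_gradient * (lon - lon_ref)
          + ph_trend_depth_gradient * z

    With the defaults this puts surface trends in the range observed in
    Galician coastal waters (about -0.0030 to -0.0040 pH yr^-1, the
    inner stations acidifying fastest) and attenuates the rate with
    depth.
    """

    seed: int = 0
    n_stations: int = 6
    depth_bins: tuple = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0))
    years: tuple = (1995, 2020)          # prediction span, calendar years inclusive
    train_years: tuple = (1976.5, 2018.7)  # decimal-year span of cruise sampling
    n_train_ph: int = 5755
    n_train_ta: int = 3850
    train_depth_range: tuple = (0.0, 50.0)
    gap_fraction: float = 0.0
    seasonal_sampling_bias: float = 0.0  # 0 = uniform over the year

    # spatial domain (Ria de Vigo box) and reference point for gradients
    lat_range: tuple = (42.0, 42.35)
    lon_range: tuple = (-9.11, -8.6)
    lon_ref: float = -8.85
    lat_ref: float = 42.2

    # pH signal ------------------------------------------------------
    ph_baseline: float = 8.08
    ph_seasonal_amplitude: float = 0.05   # loading of the seasonal part of u
    ph_weather_loading: float = 0.08      # loading of the weather part of u
    ph_trend_base: float = -0.0035        # pH yr^-1 at (lon_ref, 0 m)
    ph_trend_lon_gradient: float = -0.002   # pH yr^-1 per deg E
    ph_trend_depth_gradient: float = 2.4e-5  # pH yr^-1 per m (weakens downward)
    ph_offset_lon_gradient: float = 0.05  # pH per deg E (inner ria slightly higher)
    ph_offset_depth_gradient: float = -0.003  # pH per m

    # alkalinity signal ----------------------------------------------
    ta_intercept: float = 700.0           # umol/kg
    ta_salinity_slope: float = 46.7       # umol/kg per salinity unit
    ta_trend_per_year: float = 1.0        # umol/kg yr^-1

    # predictor fields -----------------------------------------------
    upwelling_phase: float = 0.8          # rad; shared seasonal phase of u
    temp_mean: float = 15.0
    temp_seasonal_amplitude: float = 2.5
    temp_phase: float = -1.9              # summer maximum
    temp_upwelling_loading: float = -1.2  # upwelled water is cold
    temp_depth_gradient: float = -0.05    # degC per m
    sal_mean: float = 35.2
    sal_seasonal_amplitude: float = 0.35
    sal_phase: float = -1.9               # winter rain freshens
    sal_weather_sd: float = 0.25          # river/rain variability of true S
    sal_lon_gradient: float = -1.0        # fresher toward the inner ria
    sal_depth_gradient: float = 0.01
    phosphate_mean: float = 0.6
    phosphate_upwelling_loading: float = 0.35
    nitrate_mean: float = 6.0
    nitrate_upwelling_loading: float = 3.5
    silicate_mean: float = 5.0
    silicate_upwelling_loading: float = 2.5
    nutrient_depth_gradient: float = 0.02  # fractional increase per m

    # observation noise ----------------------------------------------
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))

    t0: float = 1995.0                    # reference year for all trends

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for k, v in self.noise_sd.items():
            if v < 0:
                raise WorldSpecError(f"noise_sd[{k!r}] must be >= 0, got {v}")
        bins = list(self.depth_bins)
        if not bins:
            raise WorldSpecError("depth_bins must be non-empty")
        for (lo, hi) in bins:
            if not (0 <= lo < hi):
                raise WorldSpecError(f"depth bin ({lo}, {hi}) must satisfy 0 <= lo < hi")
        for (a, b) in zip(bins, bins[1:]):
            if a[1] > b[0]:
                raise WorldSpecError(f"depth bins {a} and {b} overlap or are out of order")
        if self.years[0] >= self.years[1]:
            raise WorldSpecError(f"years {self.years} must be increasing")
        if self.train_years[0] >= self.train_years[1]:
            raise WorldSpecError(f"train_years {self.train_years} must be increasing")
        if self.n_train_ph < 0 or self.n_train_ta < 0:
            raise WorldSpecError("n_train_ph and n_train_ta must be >= 0")
        if self.n_train_ph == 0 and self.n_train_ta == 0:
            raise WorldSpecError("n_train_ph and n_train_ta cannot both be 0")
        if not (0 <= self.gap_fraction < 1):
            raise WorldSpecError(f"gap_fraction must be in [0, 1), got {self.gap_fraction}")
        if self.n_stations < 1:
            raise WorldSpecError("n_stations must be >= 1")

    # -- planted truth accessors ---------------------------------------
    def station_coords(self) -> pd.DataFrame:
        """Station positions spaced along the ría axis (outer to inner)."""
        f = np.linspace(0.12, 0.88, self.n_stations)
        lat = self.lat_range[0] + f * (self.lat_range[1] - self.lat_range[0]) * 0.8
        lon = self.lon_range[0] + f * (self.lon_range[1] - self.lon_range[0])
        ids = [f"V{i + 1}" for i in range(self.n_stations)]
        return pd.DataFrame({"station_id": ids, "latitude": lat, "longitude": lon})

    def ph_trend(self, lon, depth):
        """Planted pH trend (pH yr^-1) at a position/depth."""
        return (
            self.ph_trend_base
            + self.ph_trend_lon_gradient * (np.asarray(lon) - self.lon_ref)
            + self.ph_trend_depth_gradient * np.asarray(depth)
        )

    def ph_offset(self, lon, depth):
        """Planted spatial pH offset (pH units) relative to ph_baseline."""
        return (
            self.ph_offset_lon_gradient * (np.asarray(lon) - self.lon_ref)
            + self.ph_offset_depth_gradient * np.asarray(depth)
        )

    def true_salinity(self, t, lon, depth, weather):
        return (
            self.sal_mean
            + self.sal_seasonal_amplitude * np.sin(2 * np.pi * np.asarray(t) + self.sal_phase)
            + self.sal_lon_gradient * (np.asarray(lon) - self.lon_ref)
            + self.sal_depth_gradient * np.asarray(depth)
            + weather
        )

    def true_ph(self, t, lon, depth, u):
        """Noiseless pH given the latent driver realization ``u``."""
        t = np.asarray(t)
        seasonal = np.sin(2 * np.pi * t + self.upwelling_phase)
        weather = u - seasonal
        return (
            self.ph_baseline
            + self.ph_offset(lon, depth)
            - self.ph_seasonal_amplitude * seasonal
            - self.ph_weather_loading * weather
            + self.ph_trend(lon, depth) * (t - self.t0)
        )

    def true_ta(self, t, salinity_true):
        return (
            self.ta_intercept
            + self.ta_salinity_slope * np.asarray(salinity_true)
            + self.ta_trend_per_year * (np.asarray(t) - self.t0)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_bins"] = [list(b) for b in self.depth_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticWorldSpec":
        d = dict(d)
        if "depth_bins" in d:
            d["depth_bins"] = tuple(tuple(b) for b in d["depth_bins"])
        for k in ("years", "train_years", "train_depth_range", "lat_range", "lon_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ----------------------------------------------------------------------
# calendar helpers

def decimal_year(dates: pd.Series) -> np.ndarray:
    """Decimal year of a datetime series (day resolution)."""
    dt = pd.DatetimeIndex(dates)
    year_start = pd.to_datetime(dt.year.astype(str) + "-01-01")
    next_start = pd.to_datetime((dt.year + 1).astype(str) + "-01-01")
    frac = (dt - year_start).days / (next_start - year_start).days
    return (dt.year + frac).to_numpy(float)


def date_from_decimal_year(t: np.ndarray) -> pd.DatetimeIndex:
    t = np.asarray(t, float)
    year = np.floor(t).astype(int)
    year_start = pd.to_datetime([f"{y}-01-01" for y in year])
    next_start = pd.to_datetime([f"{y + 1}-01-01" for y in year])
    days = np.floor((t - year) * (next_start - year_start).days).astype(int)
    return year_start + pd.to_timedelta(days, unit="D")


def iso_week(dates, clip_to_52: bool = True) -> np.ndarray:
    """ISO week number; week 53 folded into 52 for the periodic encoding."""
    w = pd.DatetimeIndex(dates).isocalendar().week.to_numpy(int)
    if clip_to_52:
        w = np.minimum(w, 52)
    return w


def weekly_dates(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """Every 7th day from Jan 1 of start_year through Dec 31 of end_year."""
    first = _date(int(start_year), 1, 1)
    last = _date(int(end_year), 12, 31)
    n = (last - first).days // 7 + 1
    return pd.DatetimeIndex([pd.Timestamp(first + timedelta(days=7 * i)) for i in range(n)])


# ----------------------------------------------------------------------

def _draw_upwelling(t: np.ndarray, weather: np.ndarray, phase: float) -> np.ndarray:
    return np.sin(2 * np.pi * t + phase) + weather


def generate_world(spec: SyntheticWorldSpec, with_truth: bool = False):
    """Generate the (training_table, prediction_table, truth) triple.

    Returns two :class:`pandas.DataFrame` objects in the canonical
    column layout (``COLUMNS``) and the spec itself as the planted
    truth.  The same spec (including seed) always regenerates
    bit-identical tables.

    With ``with_truth=True`` a fourth element is returned: a dict of
    row-aligned noiseless decompositions (``ph_true``, ``ta_true``,
    ``salinity_true`` and the latent driver realization) for both
    tables, so recovery experiments can score estimates against the
    exact planted series.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    training, train_truth = _generate_training(spec, rng)
    prediction, pred_truth = _generate_prediction(spec, rng)
    if spec.gap_fraction > 0:
        keep = rng.random(len(prediction)) >= spec.gap_fraction
        prediction = prediction.loc[keep].reset_index(drop=True)
        pred_truth = pred_truth.loc[keep].reset_index(drop=True)
    if with_truth:
        return training, prediction, spec, {
            "training": train_truth, "prediction": pred_truth}
    return training, prediction, spec


def _sample_times(spec: SyntheticWorldSpec, rng, n: int) -> np.ndarray:
    """Irregular cruise times: uniform over train_years, optionally with a
    seasonal acceptance bias favouring the upwelling season."""
    lo, hi = spec.train_years
    if spec.seasonal_sampling_bias <= 0:
        return np.sort(rng.uniform(lo, hi, n))
    out = []
    b = spec.seasonal_sampling_bias
    while len(out) < n:
        t = rng.uniform(lo, hi, n)
        p = (1 + b * np.sin(2 * np.pi * t + spec.upwelling_phase)) / (1 + b)
        t = t[rng.random(n) < p]
        out.extend(t.tolist())
    return np.sort(np.asarray(out[:n]))


def _predictor_fields(spec, rng, t, lat, lon, depth, u_weather):
    """Noiseless predictor values plus the latent driver realization."""
    u = _draw_upwelling(t, u_weather, spec.upwelling_phase)
    temp = (
        spec.temp_mean
        + spec.temp_seasonal_amplitude * np.sin(2 * np.pi * t + spec.temp_phase)
        + spec.temp_upwelling_loading * u_weather
        + spec.temp_depth_gradient * depth
    )
    sal_weather = rng.normal(0.0, spec.sal_weather_sd, len(t)) if spec.sal_weather_sd > 0 else np.zeros(len(t))
    sal = spec.true_salinity(t, lon, depth, sal_weather)
    depth_gain = 1.0 + spec.nutrient_depth_gradient * depth
    phos = (spec.phosphate_mean + spec.phosphate_upwelling_loading * u) * depth_gain
    nitr = (spec.nitrate_mean + spec.nitrate_upwelling_loading * u) * depth_gain
    sili = (spec.silicate_mean + spec.silicate_upwelling_loading * u) * depth_gain
    return u, temp, sal, phos, nitr, sili


def _assemble(spec, rng, station_id, lat, lon, depth, dates, t, u_weather,
              with_ph, with_ta):
    nz = spec.noise_sd
    n = len(t)
    u, temp, sal_true, phos, nitr, sili = _predictor_fields(
        spec, rng, t, lat, lon, depth, u_weather)

    def noisy(x, key):
        sd = nz.get(key, 0.0)
        return x + rng.normal(0.0, sd, n) if sd > 0 else x

    ph = np.full(n, np.nan)
    ta = np.full(n, np.nan)
    ph_true = spec.true_ph(t, lon, depth, u)
    ta_true = spec.true_ta(t, sal_true)
    ph[with_ph] = noisy(ph_true, "ph")[with_ph]
    ta[with_ta] = noisy(ta_true, "ta")[with_ta]

    truth_df = pd.DataFrame({
        "station_id": station_id,
        "depth_m": depth,
        "year_decimal": t,
        "ph_true": ph_true,
        "ta_true": ta_true,
        "salinity_true": sal_true,
        "upwelling": u,
    })
    df = pd.DataFrame({
        "station_id": station_id,
        "latitude": lat,
        "longitude": lon,
        "depth_m": depth,
        "date": pd.DatetimeIndex(dates).strftime("%Y-%m-%d"),
        "year_decimal": t,
        "week": iso_week(dates),
        "temperature_c": noisy(temp, "temperature"),
        "salinity": noisy(sal_true, "salinity"),
        "phosphate_umol_kg": np.maximum(noisy(phos, "phosphate"), 0.0),
        "nitrate_umol_kg": np.maximum(noisy(nitr, "nitrate"), 0.0),
        "silicate_umol_kg": np.maximum(noisy(sili, "silicate"), 0.0),
        "ph": ph,
        "ta_umol_kg": ta,
    })
    return df[COLUMNS], truth_df


def _generate_training(spec: SyntheticWorldSpec, rng) -> pd.DataFrame:
    # min(n_ph, n_ta) rows carry both labels; the remainder carry only the
    # more numerous one, giving exactly the requested counts per label.
    n = max(spec.n_train_ph, spec.n_train_ta)
    n_both = min(spec.n_train_ph, spec.n_train_ta)
    with_ph = np.zeros(n, bool)
    with_ta = np.zeros(n, bool)
    with_ph[: spec.n_train_ph] = True
    if spec.n_train_ta > 0:
        with_ta[:n_both] = True
        if spec.n_train_ta > n_both:
            with_ta[n_both:] = True  # n == n_ta > n_ph case
    t = _sample_times(spec, rng, n)
    dates = date_from_decimal_year(t)
    lat = rng.uniform(*spec.lat_range, n)
    lon = rng.uniform(*spec.lon_range, n)
    depth = rng.uniform(*spec.train_depth_range, n)
    u_sd = spec.noise_sd.get("upwelling", 0.0)
    u_weather = rng.normal(0.0, u_sd, n) if u_sd > 0 else np.zeros(n)
    station = np.array(["CR"] * n)  # cruise samples, not fixed stations
    return _assemble(spec, rng, station, lat, lon, depth, dates, t,
                     u_weather, with_ph, with_ta)


def _generate_prediction(spec: SyntheticWorldSpec, rng) -> pd.DataFrame:
    coords = spec.station_coords()
    dates = weekly_dates(spec.years[0], spec.years[1])
    t_week = decimal_year(dates)
    n_weeks = len(dates)
    # the latent driver's weather component is regional: one value per week,
    # shared by all stations and depths
    u_sd = spec.noise_sd.get("upwelling", 0.0)
    u_week = rng.normal(0.0, u_sd, n_weeks) if u_sd > 0 else np.zeros(n_weeks)

    frames, truth_frames = [], []
    mids = [0.5 * (lo + hi) for (lo, hi) in spec.depth_bins]
    for _, st in coords.iterrows():
        for mid in mids:
            n = n_weeks
            df, truth_df = _assemble(
                spec, rng,
                np.array([st.station_id] * n),
                np.full(n, st.latitude), np.full(n, st.longitude),
                np.full(n, mid), dates, t_week, u_week,
                with_ph=np.zeros(n, bool), with_ta=np.zeros(n, bool),
            )
            frames.append(df)
            truth_frames.append(truth_df)
    return (pd.concat(frames, ignore_index=True),
            pd.concat(truth_frames, ignore_index=True))
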