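"""End-to-end orchestration: data -> ensembles -> weekly series -> trends.

Stages, in order:

1. acquire data (generate the synthetic world, or read training and
   prediction tables from disk);
2. train the pH and TA committees on the labeled training table;
3. predict weekly pH and TA at every station x depth bin;
4. transform pH to hydrogen-ion concentration and normalize TA to the
   reference salinity (global empirical alpha by default, the variant
   whose slope is stable across the embayment);
5. z-score outlier filtering and seasonal-plus-trend fitting per
   stratum x variable, written as a report-style trends table.

A single master seed fans out deterministically (via
``numpy.random.SeedSequence``) to world generation, the train/test
split and every member initialization, so a rerun with the same config
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brnn, carbonate, tableio, trends
from .world import SyntheticWorldSpec, generate_world

log = logging.getLogger("riacarb")

VARIABLES = ["ph", "h", "ta", "nta"]

NORMALIZATION_METHODS = ("empirical-global", "empirical-stratum", "reference")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""
    world: SyntheticWorldSpec | None = None
    training_table: str | None = None
    prediction_table: str | None = None
    ph_hidden: list = field(default_factory=lambda: [28, 10])
    ta_hidden: list = field(default_factory=lambda: [40])
    n_members: int = brnn.ENSEMBLE_SIZE
    max_iter: int = 150
    tol: float = 1e-6
    fraction_test: float = 0.10
    normalization: str = "empirical-global"
    s_min: float = carbonate.DEFAULT_S_MIN
    confidence: float = 0.95
    z_max: float = 3.0
    output_dir: str = "results/run"
    master_seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        have_world = self.world is not None
        have_paths = self.training_table is not None or self.prediction_table is not None
        if have_world == have_paths:
            raise ConfigError(
                "exactly one of a synthetic world spec or real table paths must be set")
        if have_paths and (self.training_table is None or self.prediction_table is None):
            raise ConfigError("real-data mode needs both training_table and prediction_table")
        if self.normalization not in NORMALIZATION_METHODS:
            raise ConfigError(f"normalization must be one of {NORMALIZATION_METHODS}")
        if self.n_members < 1:
            raise ConfigError("n_members must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"] = self.world.to_dict() if self.world is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("world") is not None:
            d["world"] = SyntheticWorldSpec.from_dict(d["world"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    checksums: dict = field(default_factory=dict)
    wall_times: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict, repr=False)  # in-memory, not serialized

    def to_dict(self):
        return {"config": self.config, "seeds": self.seeds,
                "checksums": self.checksums, "wall_times": self.wall_times,
                "summaries": self.summaries}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_seeds(master_seed: int) -> dict:
    """Deterministic fan-out of the master seed to the stages."""
    state = np.random.SeedSequence(master_seed).generate_state(3)
    return {
        "world": int(state[0]) % (2 ** 31),
        "ensemble_ph": int(state[1]) % (2 ** 31),
        "ensemble_ta": int(state[2]) % (2 ** 31),
    }


def summarize_table1(model_ph: brnn.EnsembleModel,
                     model_ta: brnn.EnsembleModel) -> pd.DataFrame:
    """Member-by-member and ensemble test statistics for both targets.

    Rows: pH members 1..n + ensemble, an [H+] ensemble row obtained by
    passing the stored pH test predictions and observations through the
    hydrogen-ion transform before scoring, then the TA members and
    ensemble.  Columns: MAE, MSE, RMSE, r2.
    """
    rows = []

    def add(variable, member, m: brnn.Metrics):
        rows.append({"variable": variable, "member": member, **m.to_dict()})

    for i, m in enumerate(model_ph.member_metrics, 1):
        add("ph", str(i), m)
    add("ph", "ensemble", model_ph.ensemble_metrics)
    h_pred = carbonate.ph_to_h(model_ph.test_predictions)
    h_obs = carbonate.ph_to_h(model_ph.test_observations)
    add("h", "ensemble", brnn.evaluate(h_pred, h_obs))
    for i, m in enumerate(model_ta.member_metrics, 1):
        add("ta", str(i), m)
    add("ta", "ensemble", model_ta.ensemble_metrics)
    return pd.DataFrame(rows)


def _stratum_key(station: str, depth: float) -> str:
    return f"{station}@{depth:g}m"


def build_series(pred_table: pd.DataFrame) -> list:
    """Per-stratum TimeSeries for ph/h/ta/nta columns of the predicted
    table, ordered station-major, depth-minor."""
    out = []
    stations = sorted(pred_table["station_id"].unique())
    for st in stations:
        sub_st = pred_table[pred_table["station_id"] == st]
        for dep in sorted(sub_st["depth_m"].unique()):
            sub = sub_st[sub_st["depth_m"] == dep].sort_values("year_decimal")
            t = np.asarray(sub["year_decimal"], float)
            # guard against duplicate timestamps (strictly increasing axis)
            keep = np.concatenate([[True], np.diff(t) > 0])
            for var in VARIABLES:
                if var not in sub.columns:
                    continue
                out.append(trends.TimeSeries(
                    stratum=_stratum_key(st, dep), variable=var,
                    t=t[keep], y=np.asarray(sub[var], float)[keep]))
    return out


def normalize_ta(pred_table: pd.DataFrame, method: str,
                 alpha_fits: pd.DataFrame, s_min: float) -> np.ndarray:
    """Apply the configured TA normalization to the predicted series."""
    ta = np.asarray(pred_table["ta"], float)
    s = np.asarray(pred_table["salinity"], float)
    if method == "reference":
        return carbonate.nta_reference(ta, s, s_min=s_min)
    if method == "empirical-global":
        a = float(alpha_fits.loc[alpha_fits["stratum"] == "global", "alpha"].iloc[0])
        return carbonate.nta_empirical(ta, s, a)
    # per-stratum slopes
    out = np.empty(len(pred_table))
    key = [
        _stratum_key(st, dep)
        for st, dep in zip(pred_table["station_id"], pred_table["depth_m"])
    ]
    lookup = dict(zip(alpha_fits["stratum"], alpha_fits["alpha"]))
    for i, k in enumerate(key):
        out[i] = carbonate.nta_empirical(ta[i], s[i], lookup[k])
    return out


def run_trends_stage(pred_table: pd.DataFrame, z_max: float = 3.0,
                     confidence: float = 0.95) -> pd.DataFrame:
    """Stage 5 in isolation: trends table from a stage-4 output table."""
    return trends.trend_table(build_series(pred_table), z_max=z_max,
                              confidence=confidence)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; write artifacts under ``config.output_dir``.

    Returns the manifest; fitted models and result tables are attached
    in-memory on ``manifest.results``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.master_seed)
    manifest = RunManifest(config=config.to_dict(), seeds=seeds)
    t_start = time.time()

    def persist_manifest():
        manifest.save(out / "manifest.json")

    def checksum(name):
        manifest.checksums[name] = _sha256(out / name)

    # -- stage 1: data -------------------------------------------------
    stage = "data"
    t0 = time.time()
    try:
        if config.world is not None:
            spec = dataclasses.replace(config.world, seed=seeds["world"])
            training, prediction, truth = generate_world(spec)
            manifest.results["truth"] = truth
        else:
            training = tableio.read_table(config.training_table)
            prediction = tableio.read_table(config.prediction_table)
        tableio.write_table(training, out / "training.csv")
        tableio.write_table(prediction, out / "prediction_inputs.csv")
        checksum("training.csv")
        checksum("prediction_inputs.csv")
    except Exception as exc:
        persist_manifest()
        raise StageError(stage, exc) from exc
    manifest.wall_times[stage] = time.time() - t0
    log.info("stage %s: %d training rows, %d prediction rows",
             stage, len(training), len(prediction))

    # -- stage 2: train ensembles --------------------------------------
    stage = "train"
    t0 = time.time()
    try:
        model_ph = brnn.train_ensemble(
            training, "ph", hidden=config.ph_hidden, seed=seeds["ensemble_ph"],
            n_members=config.n_members, fraction_test=config.fraction_test,
            max_iter=config.max_iter, tol=config.tol)
        model_ta = brnn.train_ensemble(
            training, "ta", hidden=config.ta_hidden, seed=seeds["ensemble_ta"],
            n_members=config.n_members, fraction_test=config.fraction_test,
            max_iter=config.max_iter, tol=config.tol)
        model_ph.save(out / "model_ph.json")
        model_ta.save(out / "model_ta.json")
        checksum("model_ph.json")
        checksum("model_ta.json")
        table1 = summarize_table1(model_ph, model_ta)
        table1.to_csv(out / "test_metrics.csv", index=False)
        checksum("test_metrics.csv")
        manifest.results.update(model_ph=model_ph, model_ta=model_ta,
                                table1=table1)
        manifest.summaries["test_metrics"] = {
            "ph": model_ph.ensemble_metrics.to_dict(),
            "ta": model_ta.ensemble_metrics.to_dict(),
        }
        for _, row in table1[table1["member"] == "ensemble"].iterrows():
            log.info("ensemble %-3s test RMSE %.4g  r2 %.3f",
                     row["variable"], row["rmse"], row["r2"])
    except Exception as exc:
        persist_manifest()
        raise StageError(stage, exc) from exc
    manifest.wall_times[stage] = time.time() - t0

    # -- stage 3: weekly projections -----------------------------------
    stage = "predict"
    t0 = time.time()
    try:
        pred = prediction.drop(columns=["ph", "ta_umol_kg"])
        pred["ph"] = brnn.predict_ensemble(model_ph, prediction)
        pred["ta"] = brnn.predict_ensemble(model_ta, prediction)
    except Exception as exc:
        persist_manifest()
        raise StageError(stage, exc) from exc
    manifest.wall_times[stage] = time.time() - t0

    # -- stage 4: transforms and normalization -------------------------
    stage = "transform"
    t0 = time.time()
    try:
        pred["h"] = carbonate.ph_to_h(pred["ph"])
        alpha_fits = carbonate.alpha_table(pred, ta_col="ta")
        pred["nta"] = normalize_ta(pred, config.normalization, alpha_fits,
                                   config.s_min)
        alpha_fits.to_csv(out / "alpha.csv", index=False)
        pred.to_csv(out / "predicted_series.csv", index=False)
        checksum("alpha.csv")
        checksum("predicted_series.csv")
        g = alpha_fits[alpha_fits["stratum"] == "global"].iloc[0]
        manifest.summaries["alpha_global"] = {"alpha": float(g["alpha"]),
                                              "r2": float(g["r2"])}
        manifest.results.update(predicted=pred, alpha=alpha_fits)
        log.info("global alpha %.3g (r2 %.3f)", g["alpha"], g["r2"])
    except Exception as exc:
        persist_manifest()
        raise StageError(stage, exc) from exc
    manifest.wall_times[stage] = time.time() - t0

    # -- stage 5: trends -----------------------------------------------
    stage = "trends"
    t0 = time.time()
    try:
        trend_tab = run_trends_stage(pred, z_max=config.z_max,
                                     confidence=config.confidence)
        trend_tab.to_csv(out / "trends.csv", index=False)
        trends.format_trend_table(trend_tab).to_csv(
            out / "trends_report.csv", index=False)
        checksum("trends.csv")
        checksum("trends_report.csv")
        manifest.results["trends"] = trend_tab
        ph_rows = trend_tab[trend_tab["variable"] == "ph"]
        manifest.summaries["trends"] = {
            "n_series": int(len(trend_tab)),
            "n_failed": int((trend_tab["error"] != "").sum()),
            "ph_trend_mean": float(ph_rows["B"].mean()),
        }
    except Exception as exc:
        persist_manifest()
        raise StageError(stage, exc) from exc
    manifest.wall_times[stage] = time.time() - t0
    manifest.wall_times["total"] = time.time() - t_start
    persist_manifest()
    return manifest
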