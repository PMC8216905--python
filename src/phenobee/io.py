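"""CSV interchange, schema validation, and the reproducible pipeline driver.

All stage outputs are plain CSV with ISO-8601 timestamps. Every pipeline
run writes a manifest (config snapshot, seed, per-file SHA-256 digests) so
a run can be reproduced byte-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import phenostats as _stats
from . import scenario as _scenario
from . import synthetic as _synthetic

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "RunManifest",
    "read_telemetry",
    "write_telemetry",
    "read_events",
    "write_events",
    "run_pipeline",
]

log = logging.getLogger("phenobee")

TELEMETRY_COLUMNS = ["colony_id", "sensor_id", "timestamp", "temp_c"]
EVENT_COLUMNS = [
    "colony_id", "time", "event", "censor_cause",
    "temp_regime", "light_regime", "origin_swarm", "brood_at_start",
]


class SchemaError(ValueError):
    """A file violates the documented column schema or a type invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what}: extra column(s) preserved: {extra}", stacklevel=3)


def read_telemetry(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a telemetry CSV (colony_id, sensor_id, timestamp, temp_c).

    Validation enforces the 3-hour sampling grid, the 0.5 degC logger
    quantization, and sensor ids 1..12; extra columns are preserved with a
    warning.
    """
    df = pd.read_csv(path)
    _require_columns(df, TELEMETRY_COLUMNS, "telemetry")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if validate:
        ts = df["timestamp"]
        off_grid = (ts.dt.hour % 3 != 0) | (ts.dt.minute != 0) | (ts.dt.second != 0)
        if off_grid.any():
            raise SchemaError(
                f"telemetry: {int(off_grid.sum())} timestamp(s) off the 3-hour grid"
            )
        twice = df["temp_c"].to_numpy(dtype=float) * 2.0
        if not np.allclose(twice, np.round(twice), atol=1e-9):
            raise SchemaError("telemetry: temp_c not quantized to 0.5 degC")
        bad_sensor = ~df["sensor_id"].isin(range(1, 13))
        if bad_sensor.any():
            raise SchemaError("telemetry: sensor_id outside 1..12")
    return df


def write_telemetry(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a survival-record CSV; validates event coding and time >= 1."""
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, "events")
    if not df["event"].isin([0, 1]).all():
        raise SchemaError("events: event must be 0 or 1")
    if (df["time"] < 1).any():
        raise SchemaError("events: time must be >= 1")
    for col in ("origin_swarm", "brood_at_start"):
        df[col] = df[col].astype(bool)
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full pipeline run."""

    seed: int = 1
    start: dt.date = _scenario.EXPERIMENT_START
    end: dt.date = _scenario.EXPERIMENT_END
    warming_offset_c: float = 4.0
    daily_amplitude_c: float = 3.0
    ramp_h: float = 1.0
    light_regimes: tuple[str, ...] = ("CD", "CEP", "NEP")
    sites: dict = field(
        default_factory=lambda: {"CEP": _scenario.WURZBURG, "NEP": _scenario.SNASA}
    )
    simulation: _synthetic.SimulationConfig | None = None
    thresholds: _detect.DetectionThresholds = field(
        default_factory=_detect.DetectionThresholds
    )

    def validate(self) -> None:
        for regime in self.light_regimes:
            if regime != "CD" and regime not in self.sites:
                raise SchemaError(f"light regime {regime} has no site configured")
        if self.end <= self.start:
            raise SchemaError("end date must follow start date")

    def resolved_simulation(self) -> _synthetic.SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return _synthetic.SimulationConfig(seed=self.seed)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["start"], d["end"] = self.start.isoformat(), self.end.isoformat()
        d["sites"] = {k: dataclasses.asdict(v) for k, v in self.sites.items()}
        d["simulation"] = dataclasses.asdict(self.resolved_simulation())
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    timestamp: str
    config_hash: str
    seed: int
    stages: dict  # stage -> {file: digest}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _write_model_summaries(results: list, out: Path) -> list[Path]:
    frames = []
    written = []
    for res in results:
        tab = res.anova.copy()
        tab.insert(0, "model", res.name)
        frames.append(tab)
        if res.contrasts is not None:
            p = out / f"contrasts_{res.name}.csv"
            res.contrasts.to_csv(p, index=False)
            written.append(p)
    summary = pd.concat(frames, ignore_index=True)
    p = out / "model_summaries.csv"
    summary.to_csv(p, index=False)
    written.append(p)

    report = out / "report.txt"
    with report.open("w") as fh:
        for res in results:
            fh.write(f"== {res.name} ==\n")
            fh.write(res.anova.to_string(index=False))
            fh.write("\n")
            for note in res.notes:
                fh.write(f"note: {note}\n")
            fh.write("\n")
    written.append(report)
    return written


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run scenario -> simulate -> detect -> analyze and write a manifest.

    Deterministic: the same config (seed included) produces byte-identical
    stage outputs. A stage failure leaves earlier outputs in place with a
    ``.partial`` marker file naming the failed stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, str]] = {}
    marker = out / ".partial"
    marker.write_text("pipeline running")

    def record(stage: str, files: list[Path]) -> None:
        stages[stage] = {f.name: _sha256(f) for f in files}
        log.info("stage %s: wrote %d file(s)", stage, len(files))

    try:
        # -- scenario ------------------------------------------------------
        n_days = (config.end - config.start).days + 1
        n_weeks = int(np.ceil(n_days / 7))
        clim = _scenario.sinusoidal_climatology()
        current = _scenario.build_weekly_means(clim)
        regimes = {
            "current": current,
            "future": _scenario.apply_warming_offset(current, config.warming_offset_c),
        }
        files = []
        for name, regime in regimes.items():
            profile = _scenario.expand_hourly(
                regime, config.start, n_weeks, daily_amplitude=config.daily_amplitude_c
            )
            tab = profile.table.copy()
            tab.insert(1, "regime", name)
            p = out / f"setpoints_{name}.csv"
            tab.to_csv(p, index=False)
            files.append(p)
        for lab in config.light_regimes:
            sched = _scenario.build_photoperiod_schedule(
                lab, config.sites.get(lab), (config.start, config.end), config.ramp_h
            )
            p = out / f"photoperiod_{lab}.csv"
            sched.to_table().to_csv(p, index=False)
            files.append(p)
        record("scenario", files)

        # -- simulate ------------------------------------------------------
        sim_cfg = config.resolved_simulation()
        bundle = _synthetic.generate_study(sim_cfg, config.start, config.end)
        files = []
        p = out / "telemetry.csv"
        write_telemetry(bundle.telemetry, p)
        files.append(p)
        for name, df in [
            ("flowering", bundle.flowering),
            ("heights", bundle.heights),
            ("weights", bundle.weights),
            ("colonies", bundle.colonies),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            files.append(p)
        record("simulate", files)

        # -- detect --------------------------------------------------------
        telemetry = read_telemetry(out / "telemetry.csv")
        onsets, deaths, prop_rows, daily_frames, call_frames = {}, {}, [], [], []
        for colony_id, samples in telemetry.groupby("colony_id"):
            res = _detect.analyze_colony(samples, config.thresholds)
            onsets[colony_id] = res["onset"]
            deaths[colony_id] = res["death"]
            daily_frames.append(res["daily"])
            call_frames.append(res["calls"].assign(colony_id=colony_id))
            prop_rows.append(
                {
                    "colony_id": colony_id,
                    "n_brood_days": res["n_brood_days"],
                    "n_days": res["n_days"],
                    "brood_fraction": res["brood_fraction"],
                }
            )
        survival = _detect.build_survival_records(
            onsets, deaths, config.start, config.end, bundle.colonies
        )
        log.info(
            "detect: %d colonies, %d onsets, %d deaths",
            len(onsets),
            sum(o is not None for o in onsets.values()),
            sum(d is not None for d in deaths.values()),
        )
        files = []
        for name, df in [
            ("daily_stats", pd.concat(daily_frames, ignore_index=True)),
            ("brood_calls", pd.concat(call_frames, ignore_index=True)),
            ("brood_proportions", pd.DataFrame(prop_rows)),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            files.append(p)
        p = out / "survival_records.csv"
        write_events(survival, p)
        files.append(p)
        record("detect", files)

        # -- analyze -------------------------------------------------------
        proportions = pd.DataFrame(prop_rows).merge(bundle.colonies, on="colony_id")
        pot_counts = (
            bundle.flowering.groupby(["pot_id", "temp_regime", "light_regime"])
            .agg(flowered=("event", "sum"), total=("event", "count"))
            .reset_index()
        )
        results = [
            _stats.fit_flowering_cox(bundle.flowering),
            _stats.fit_flowering_proportion_glm(pot_counts),
            _stats.fit_height_lmm(bundle.heights),
            _stats.fit_onset_cox(survival),
            _stats.fit_brood_proportion_glm(proportions),
            _stats.fit_weight_model(
                _stats.weight_status_means(bundle.weights, bundle.colonies)
            ),
        ]
        for regime in ("current", "future"):
            results.append(
                _stats.fit_cross_species_cox(bundle.flowering, survival, regime)
            )
        record("analyze", _write_model_summaries(results, out))
    except Exception as err:
        marker.write_text(f"failed stage after: {list(stages)}; error: {err}")
        raise
    marker.unlink()

    manifest = RunManifest(
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
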