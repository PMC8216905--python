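"""Seeded generators for chamber-like datasets.

These generators realize the statistical structure the detection and
modelling stages assume — they are not mechanistic models of bee
thermoregulation or crocus physiology:

* comb-temperature telemetry: 12 sensors per colony sampled every 3 h,
  0.5 degC logger quantization, a low-amplitude >=32 degC plateau on the
  warmest sensor during brood episodes, a high-amplitude ~24 degC winter
  cluster otherwise, and an exponential decay to <=17 degC after colony
  death;
* flowering observations: a discrete-time weekly hazard increasing with
  accumulated thermal time and day length, with a never-flowering fraction
  under constant darkness;
* plant heights and daily hive weight changes with configurable cell means.

A single seed drives everything; per-unit streams are derived by stable
sub-seeding (``numpy`` ``SeedSequence`` spawn keys), so adding units does
not perturb existing ones.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .scenario import (
    EXPERIMENT_END,
    EXPERIMENT_START,
    SNASA,
    WURZBURG,
    HourlyTemperatureProfile,
    PhotoperiodSchedule,
    WeeklyRegime,
    apply_warming_offset,
    build_photoperiod_schedule,
    build_weekly_means,
    day_length,
    expand_hourly,
    experiment_weekly_means,
    sinusoidal_climatology,
)

__all__ = [
    "SimulationConfig",
    "BroodPlan",
    "StudyBundle",
    "quantize_half_degree",
    "simulate_colony_telemetry",
    "simulate_flowering",
    "simulate_heights",
    "simulate_weights",
    "random_brood_plan",
    "generate_study",
]

TEMP_REGIMES = ("current", "future")
LIGHT_REGIMES = ("CD", "CEP", "NEP")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults mirror the study's design and biology.

    Temperatures in degC, weights in grams, hazards per week, rates per day.
    """

    seed: int = 0
    n_colonies_per_cell: int = 4
    n_pots_per_cell: int = 4
    n_bulbs_per_pot: int = 4
    brood_core_temp: float = 34.5
    brood_core_amplitude: float = 1.0
    cluster_temp: float = 24.0
    cluster_amplitude: float = 4.0
    sensor_gradient: float = 1.5  # degC drop per sensor rank below the core
    sensor_noise_sd: float = 0.2
    death_decay_rate: float = 1.0  # per day, decay toward ambient after death
    flowering_base_hazard: float = 0.02
    beta_thermal: float = 0.025  # per degC-week of accumulated thermal time
    beta_photoperiod: float = 0.08  # per hour of day length
    dark_nonflower_prob: float = 0.25
    weight_loss_brood: float = 28.84  # g/day lost while rearing brood
    weight_loss_nobrood: float = 20.15
    weight_noise_sd: float = 2.0
    height_base_cm: float = 9.0
    height_future_bonus_cm: float = 2.0
    height_cd_etiolation_cm: float = 4.0
    height_cep_bonus_cm: float = 1.5
    height_arena_sd: float = 0.6  # between-arena random intercept
    height_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dark_nonflower_prob <= 1.0:
            raise ValueError("dark_nonflower_prob must be in [0, 1]")
        for name in ("brood_core_temp", "cluster_temp", "sensor_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class BroodPlan:
    """Ground-truth brood activity for one simulated colony."""

    colony_id: str
    episodes: tuple[tuple[int, int], ...]  # (onset day, duration days), day 1-based
    death_day: int | None = None

    def __post_init__(self) -> None:
        last_end = 0
        for onset, dur in self.episodes:
            if onset <= last_end:
                raise ValueError("episodes must be ordered and non-overlapping")
            if dur < 1:
                raise ValueError("episode duration must be >= 1 day")
            last_end = onset + dur - 1
        if self.death_day is not None and self.episodes:
            if self.death_day <= self.episodes[-1][0]:
                raise ValueError("death_day must follow the last episode onset")

    def is_brood_day(self, day: int) -> bool:
        if self.death_day is not None and day >= self.death_day:
            return False
        return any(onset <= day < onset + dur for onset, dur in self.episodes)

    def onset_day(self, min_run: int = 3) -> int | None:
        """First day of the earliest episode at least *min_run* days long
        (truncated at death), i.e. what the detector should recover."""
        for onset, dur in self.episodes:
            end = onset + dur - 1
            if self.death_day is not None:
                end = min(end, self.death_day - 1)
            if end - onset + 1 >= min_run:
                return onset
        return None


def quantize_half_degree(temps: np.ndarray) -> np.ndarray:
    """Round to the 0.5 degC logger resolution (2*T integer)."""
    return np.round(np.asarray(temps, dtype=float) * 2.0) / 2.0


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_colony_telemetry(
    config: SimulationConfig,
    profile: HourlyTemperatureProfile,
    plan: BroodPlan,
    rng: np.random.Generator | None = None,
    quantize: bool = True,
) -> pd.DataFrame:
    """Generate 3-hourly quantized sensor samples for one colony.

    During brood episodes the designated core sensor holds
    ``brood_core_temp`` with daily range ``brood_core_amplitude``; outside
    them the warmest sensor follows the winter cluster
    (``cluster_temp`` +- ``cluster_amplitude``/2, so non-brood days fail
    the 2 degC amplitude rule). Remaining sensors sit ``sensor_gradient``
    degC per rank lower, floored at the chamber setpoint. From
    ``death_day`` on, all sensors decay exponentially toward ambient and
    are capped at 17 degC. Gaussian noise is added before quantization.

    Returns columns ``colony_id, sensor_id, timestamp, temp_c``.
    """
    tab = profile.table
    if tab.empty:
        raise ValueError("temperature profile is empty")
    if rng is None:
        rng = _sub_rng(config.seed, 0)

    grid = tab[tab["timestamp"].dt.hour % 3 == 0]
    ts = grid["timestamp"].to_numpy()
    ambient = grid["setpoint_c"].to_numpy(dtype=float)
    hours = grid["timestamp"].dt.hour.to_numpy()
    start_date = tab["timestamp"].iloc[0].date()
    days = np.array([(t.date() - start_date).days + 1 for t in grid["timestamp"]])

    # Daily shape: minimum at 00:00, maximum at 12:00, like the chamber.
    shape = -np.cos(2.0 * np.pi * hours / 24.0) / 2.0  # in [-0.5, 0.5]

    brood = np.array([plan.is_brood_day(d) for d in days])
    dead_from = plan.death_day
    dead = np.zeros_like(brood) if dead_from is None else days >= dead_from

    core_alive = np.where(
        brood,
        config.brood_core_temp + config.brood_core_amplitude * shape,
        config.cluster_temp + config.cluster_amplitude * shape,
    )

    # Sensor ids 1..12 assigned to ranks by a per-colony permutation so the
    # warmest sensor is not always sensor 1.
    sensor_of_rank = rng.permutation(np.arange(1, 13))

    frames = []
    for rank in range(12):
        temp = np.maximum(core_alive - config.sensor_gradient * rank, ambient)
        if dead_from is not None:
            elapsed = days + hours / 24.0 - dead_from
            decay = ambient + (temp - ambient) * np.exp(
                -config.death_decay_rate * np.maximum(elapsed, 0.0)
            )
            temp = np.where(dead, np.minimum(decay, 17.0), temp)
        if config.sensor_noise_sd > 0:
            temp = temp + rng.normal(0.0, config.sensor_noise_sd, size=temp.shape)
        if quantize:
            temp = quantize_half_degree(temp)
        if dead_from is not None:
            temp = np.where(dead, np.minimum(temp, 17.0), temp)
        frames.append(
            pd.DataFrame(
                {
                    "colony_id": plan.colony_id,
                    "sensor_id": sensor_of_rank[rank],
                    "timestamp": ts,
                    "temp_c": temp,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sensor_id", "timestamp"], ignore_index=True)


def simulate_flowering(
    config: SimulationConfig,
    regime: WeeklyRegime,
    schedule: PhotoperiodSchedule,
    cell_label: str | None = None,
    n_pots: int | None = None,
    n_bulbs_per_pot: int | None = None,
    start: dt.date = EXPERIMENT_START,
    n_weeks: int = 22,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw censored flowering weeks for one treatment cell.

    The weekly flowering hazard is
    ``h(w) = 1 - exp(-h0 * exp(bT * GDD(w) + bP * L(w)))`` with ``GDD(w)``
    the cumulative weekly mean temperature above 0 degC and ``L(w)`` the
    day length (hours) at the week's first day. Under constant darkness an
    independent Bernoulli(``dark_nonflower_prob``) marks bulbs that never
    flower; all non-events are censored at week ``n_weeks``.
    """
    if rng is None:
        rng = _sub_rng(config.seed, 1)
    n_pots = config.n_pots_per_cell if n_pots is None else n_pots
    n_bulbs = config.n_bulbs_per_pot if n_bulbs_per_pot is None else n_bulbs_per_pot
    cell = cell_label or f"{regime.regime_label}-{schedule.regime_label}"

    wm = experiment_weekly_means(regime, start, n_weeks)
    gdd = np.cumsum(np.maximum(wm, 0.0))
    daylen = np.array(
        [day_length(schedule, start + dt.timedelta(days=7 * i)) for i in range(n_weeks)]
    )
    hazard = 1.0 - np.exp(
        -config.flowering_base_hazard
        * np.exp(config.beta_thermal * gdd + config.beta_photoperiod * daylen)
    )

    rows = []
    for p in range(n_pots):
        pot_id = f"{cell}-P{p + 1}"
        arena_id = f"{cell}-A{p + 1}"
        for b in range(n_bulbs):
            week, event = n_weeks, 0
            never = (
                schedule.regime_label == "CD"
                and rng.random() < config.dark_nonflower_prob
            )
            if not never:
                draws = rng.random(n_weeks) < hazard
                if draws.any():
                    week, event = int(np.argmax(draws)) + 1, 1
            rows.append(
                {
                    "bulb_id": f"{pot_id}-B{b + 1}",
                    "pot_id": pot_id,
                    "arena_id": arena_id,
                    "temp_regime": regime.regime_label,
                    "light_regime": schedule.regime_label,
                    "week": week,
                    "event": event,
                }
            )
    return pd.DataFrame(rows)


def simulate_heights(
    config: SimulationConfig,
    cells: list[tuple[str, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Final plant heights, Normal per treatment cell.

    Cell mean = base + future bonus + CD etiolation + CEP bonus, a simple
    additive stand-in for the growth patterns the height model tests.
    """
    if rng is None:
        rng = _sub_rng(config.seed, 2)
    if cells is None:
        cells = [(t, l) for t in TEMP_REGIMES for l in LIGHT_REGIMES]
    rows = []
    for temp_regime, light_regime in cells:
        mean = config.height_base_cm
        if temp_regime == "future":
            mean += config.height_future_bonus_cm
        if light_regime == "CD":
            mean += config.height_cd_etiolation_cm
        elif light_regime == "CEP":
            mean += config.height_cep_bonus_cm
        cell = f"{temp_regime}-{light_regime}"
        for p in range(config.n_pots_per_cell):
            arena_effect = rng.normal(0.0, config.height_arena_sd)
            for b in range(config.n_bulbs_per_pot):
                rows.append(
                    {
                        "bulb_id": f"{cell}-P{p + 1}-B{b + 1}",
                        "arena_id": f"{cell}-A{p + 1}",
                        "temp_regime": temp_regime,
                        "light_regime": light_regime,
                        "height_cm": mean
                        + arena_effect
                        + rng.normal(0.0, config.height_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_weights(
    config: SimulationConfig,
    plan: BroodPlan,
    n_days: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily hive weight changes for one colony.

    Change = -``weight_loss_brood`` g on brood days, -``weight_loss_nobrood``
    otherwise, plus Gaussian noise; days from death on are omitted.
    """
    if rng is None:
        rng = _sub_rng(config.seed, 3)
    last = n_days if plan.death_day is None else min(n_days, plan.death_day - 1)
    rows = []
    for day in range(1, last + 1):
        brood = plan.is_brood_day(day)
        loss = config.weight_loss_brood if brood else config.weight_loss_nobrood
        rows.append(
            {
                "colony_id": plan.colony_id,
                "day": day,
                "brood": brood,
                "weight_change_g": -loss + rng.normal(0.0, config.weight_noise_sd),
            }
        )
    return pd.DataFrame(rows)


def random_brood_plan(
    colony_id: str,
    rng: np.random.Generator,
    n_days: int = 154,
    p_no_brood: float = 0.25,
    p_death: float = 0.15,
    onset_range: tuple[int, int] = (20, 100),
    duration_range: tuple[int, int] = (10, 40),
) -> BroodPlan:
    """Draw a plausible colony history: possibly no brood at all, one or two
    episodes (>= 3 days each), and occasional death after the last onset."""
    episodes: list[tuple[int, int]] = []
    if rng.random() >= p_no_brood:
        onset = int(rng.integers(onset_range[0], onset_range[1] + 1))
        dur = int(rng.integers(duration_range[0], duration_range[1] + 1))
        dur = min(dur, n_days - onset + 1)
        episodes.append((onset, dur))
        gap_start = onset + dur + int(rng.integers(3, 15))
        if rng.random() < 0.4 and gap_start + 3 <= n_days:
            dur2 = int(rng.integers(3, duration_range[1] + 1))
            dur2 = min(dur2, n_days - gap_start + 1)
            episodes.append((gap_start, dur2))
    death_day = None
    if rng.random() < p_death:
        lo = episodes[-1][0] + 1 if episodes else 10
        if lo < n_days - 5:
            death_day = int(rng.integers(lo, n_days - 5))
    return BroodPlan(colony_id=colony_id, episodes=tuple(episodes), death_day=death_day)


@dataclass
class StudyBundle:
    """Full synthetic study: telemetry, ground truth, and observation tables."""

    telemetry: pd.DataFrame
    plans: dict[str, BroodPlan]
    colonies: pd.DataFrame  # colony_id, arena_id, covariates
    flowering: pd.DataFrame
    heights: pd.DataFrame
    weights: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def generate_study(
    config: SimulationConfig,
    start: dt.date = EXPERIMENT_START,
    end: dt.date = EXPERIMENT_END,
) -> StudyBundle:
    """Generate the full six-cell study (2 temperature x 3 light regimes).

    Defaults give 6 cells x 4 colonies = 24 colonies and 6 x 16 = 96 bulbs,
    the study's design. Deterministic for a given config (seed included).
    """
    n_days = (end - start).days + 1
    n_weeks = int(np.ceil(n_days / 7))

    clim = sinusoidal_climatology()
    current = build_weekly_means(clim)
    regimes = {"current": current, "future": apply_warming_offset(current, 4.0)}
    profiles = {
        name: expand_hourly(reg, start, n_weeks) for name, reg in regimes.items()
    }
    sites = {"CD": None, "CEP": WURZBURG, "NEP": SNASA}
    schedules = {
        lab: build_photoperiod_schedule(lab, sites[lab], (start, start + dt.timedelta(days=7 * n_weeks)))
        for lab in LIGHT_REGIMES
    }

    telemetry, weights, flowering = [], [], []
    plans: dict[str, BroodPlan] = {}
    colony_rows = []
    for ti, temp_regime in enumerate(TEMP_REGIMES):
        for li, light_regime in enumerate(LIGHT_REGIMES):
            cell = f"{temp_regime}-{light_regime}"
            cell_key = ti * len(LIGHT_REGIMES) + li
            for c in range(config.n_colonies_per_cell):
                colony_id = f"{cell}-C{c + 1}"
                rng = _sub_rng(config.seed, 10, cell_key, c)
                plan = random_brood_plan(colony_id, rng, n_days=n_days)
                plans[colony_id] = plan
                telemetry.append(
                    simulate_colony_telemetry(config, profiles[temp_regime], plan, rng)
                )
                weights.append(simulate_weights(config, plan, n_days, rng))
                colony_rows.append(
                    {
                        "colony_id": colony_id,
                        "arena_id": f"{cell}-A{c + 1}",
                        "temp_regime": temp_regime,
                        "light_regime": light_regime,
                        # one artificial swarm per cell, like the study
                        "origin_swarm": c == 0,
                        "brood_at_start": bool(rng.random() < 0.3),
                    }
                )
            flowering.append(
                simulate_flowering(
                    config,
                    regimes[temp_regime],
                    schedules[light_regime],
                    cell_label=cell,
                    start=start,
                    n_weeks=n_weeks,
                    rng=_sub_rng(config.seed, 20, cell_key),
                )
            )
    heights = simulate_heights(config, rng=_sub_rng(config.seed, 30))

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "start": start.isoformat(),
        "end": end.isoformat(),
        "n_days": n_days,
        "n_weeks": n_weeks,
        "n_colonies": len(plans),
        "n_bulbs": sum(len(f) for f in flowering),
    }
    return StudyBundle(
        telemetry=pd.concat(telemetry, ignore_index=True),
        plans=plans,
        colonies=pd.DataFrame(colony_rows),
        flowering=pd.concat(flowering, ignore_index=True),
        heights=heights,
        weights=pd.concat(weights, ignore_index=True),
        manifest=manifest,
    )
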