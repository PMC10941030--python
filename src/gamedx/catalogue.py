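"""Formal definitions of the four insole-controlled games.

A gaming session is steered entirely by plantar pressure measured with
sensor-equipped insoles (eight force-sensing resistors per foot, 3.4 mbar
resolution over 250 mbar - 7 bar).  Four games are played in sequence:

* **AC** (Apple-Catch)    - steer a carriage with forefoot pressure to catch
  falling apples; probes reaction time and precision.
* **BF** (Balloon-Flying) - control a balloon's altitude with the pressure
  differential between the two forefeet; probes bilateral coordination.
* **CP** (Cross-Pressure) - hold a prescribed pressure band on an indicated
  foot region for a set duration (25 s timeout); probes sensation and
  endurance.
* **IJ** (Island-Jump)    - produce a peak pressure inside a target band to
  make a bird jump between islands; failed attempts are repeated; probes
  graded force control.

This module defines the session configuration (sensor layout, calibration,
task schedules), the grouping of tasks into task combinations (TCs), and the
enumeration of the feature catalogue (primary per-task features plus
sum/mean/SD secondaries per TC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

GAMES = ("AC", "BF", "CP", "IJ")
FEET = ("left", "right")
REGIONS = ("heel", "lateral_arch", "met1", "met3", "met5", "hallux", "toes")

#: Sensor grid of the force-sensing resistors.
PRESSURE_MIN = 250.0  # mbar
PRESSURE_MAX = 7000.0  # mbar
QUANTIZATION_STEP = 3.4  # mbar

#: Default per-game primary ("base") feature labels.
DEFAULT_BASE_FEATURES: dict[str, tuple[str, ...]] = {
    "AC": ("reaction_time", "catch_success", "positional_error", "overshoot_count"),
    "BF": ("collision_count", "points_collected", "altitude_tracking_rmse",
           "correction_latency"),
    "CP": ("time_to_valid_hold", "hold_stability_sd", "timeout_flag",
           "band_exceedance_fraction"),
    "IJ": ("attempts_to_success", "peak_pressure_error", "jump_success",
           "pressure_rise_time"),
}


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


@dataclass(frozen=True)
class SensorLayout:
    """Eight pressure sensors of one insole and their anatomical regions."""

    foot: str
    sensor_ids: tuple[str, ...]
    region: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.foot not in FEET:
            raise ConfigurationError(f"foot must be left/right, got {self.foot!r}")
        if len(self.sensor_ids) != 8:
            raise ConfigurationError(
                f"exactly 8 sensors required per foot, got {len(self.sensor_ids)}")
        covered = set(self.region.values())
        missing = set(REGIONS) - covered
        if missing:
            raise ConfigurationError(f"regions not covered by layout: {sorted(missing)}")

    def sensors_in(self, region: str) -> list[str]:
        return [s for s in self.sensor_ids if self.region[s] == region]


def default_layout(foot: str) -> SensorLayout:
    """Heel, lateral arch, metatarsals 1/3/5, hallux, toes + one aux sensor."""
    prefix = "L" if foot == "left" else "R"
    ids = tuple(f"{prefix}{i}" for i in range(1, 9))
    regions = ("heel", "lateral_arch", "met1", "met3", "met5", "hallux", "toes", "aux")
    return SensorLayout(foot=foot, sensor_ids=ids,
                        region=dict(zip(ids, regions)))


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-sensor rest (baseline) and voluntary-maximum pressures in mbar."""

    baseline: Mapping[str, float]
    maximum: Mapping[str, float]

    def __post_init__(self) -> None:
        for sid, lo in self.baseline.items():
            hi = self.maximum.get(sid)
            if hi is None:
                raise ConfigurationError(f"maximum missing for sensor {sid}")
            if not (PRESSURE_MIN <= lo < hi <= PRESSURE_MAX):
                raise ConfigurationError(
                    f"calibration for {sid} must satisfy "
                    f"{PRESSURE_MIN} <= baseline < maximum <= {PRESSURE_MAX}, "
                    f"got ({lo}, {hi})")


def default_calibration(*layouts: SensorLayout,
                        baseline: float = 300.0,
                        maximum: float = 3000.0) -> CalibrationProfile:
    ids = [s for lay in layouts for s in lay.sensor_ids]
    return CalibrationProfile(baseline={s: baseline for s in ids},
                              maximum={s: maximum for s in ids})


def derive_calibration(rest: Mapping[str, Sequence[float]],
                       press: Mapping[str, Sequence[float]]) -> CalibrationProfile:
    """Derive (baseline, maximum) from rest / maximal-press recordings.

    Baseline is the median rest pressure, maximum the 95th percentile of the
    press recording, both snapped into the sensor's valid range.
    """
    base, mx = {}, {}
    for sid in rest:
        lo = float(np.clip(np.median(rest[sid]), PRESSURE_MIN, PRESSURE_MAX - 1))
        hi = float(np.clip(np.percentile(press[sid], 95), lo + 1, PRESSURE_MAX))
        base[sid], mx[sid] = lo, hi
    return CalibrationProfile(baseline=base, maximum=mx)


@dataclass(frozen=True)
class TaskSpec:
    """One task of one game: target sensors, pressure band, timing."""

    game: str
    task_index: int
    controlling_foot: str  # left | right | both
    target_sensors: tuple[str, ...]
    target_band: tuple[float, float]  # normalized pressure
    timeout: float  # s
    stimulus_onset: float = 0.5  # s from task start
    hold_duration: float = 0.0  # s, CP only

    def __post_init__(self) -> None:
        lo, hi = self.target_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                f"target_band must satisfy 0 <= low < high <= 1, got {self.target_band}")
        if self.timeout <= 0:
            raise ConfigurationError("timeout must be positive")
        if self.game == "CP" and self.hold_duration <= 0:
            raise ConfigurationError("CP tasks require hold_duration > 0")

    @property
    def band_center(self) -> float:
        return 0.5 * (self.target_band[0] + self.target_band[1])

    @property
    def band_width(self) -> float:
        return self.target_band[1] - self.target_band[0]


@dataclass(frozen=True)
class TaskCombination:
    """A set of same-game tasks with analogous specifications.

    TCLk / TCRk collect left- and right-foot-controlled tasks (mirror sets),
    TCBk collects bilateral tasks.  Primary features are aggregated over the
    member tasks into sum/mean/SD secondary features.
    """

    id: str
    game: str
    member_tasks: tuple[int, ...]
    foot_scope: str

    def __post_init__(self) -> None:
        if not self.member_tasks:
            raise ConfigurationError(f"TC {self.id} has no member tasks")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    kind: str  # primary | secondary
    game: str
    source: str  # "TS<i>" or TC id
    base_feature: str
    aggregation: str  # none | sum | mean | sd

    def __post_init__(self) -> None:
        if self.kind == "primary" and self.aggregation != "none":
            raise ConfigurationError("primary features carry no aggregation")
        if self.kind == "secondary" and self.aggregation not in ("sum", "mean", "sd"):
            raise ConfigurationError("secondary aggregation must be sum/mean/sd")


@dataclass(frozen=True)
class GameSessionConfig:
    game_order: tuple[str, ...]
    tasks: Mapping[str, tuple[TaskSpec, ...]]
    sensor_layout: Mapping[str, SensorLayout]
    calibration: CalibrationProfile
    sampling_rate: float = 200.0  # Hz
    session_time_budget: float = 900.0  # s ("completed within 15 minutes")
    quantization_step: float = QUANTIZATION_STEP
    pressure_range: tuple[float, float] = (PRESSURE_MIN, PRESSURE_MAX)
    base_features: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FEATURES))

    def __post_init__(self) -> None:
        if sorted(self.game_order) != sorted(GAMES):
            raise ConfigurationError(
                f"game_order must be a permutation of {GAMES}, got {self.game_order}")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        for game, specs in self.tasks.items():
            if len(specs) < 1:
                raise ConfigurationError(f"game {game} must have at least one task")
            for spec in specs:
                if spec.game != game:
                    raise ConfigurationError(
                        f"task {spec.task_index} filed under {game} but tagged {spec.game}")
        for game, feats in self.base_features.items():
            if len(set(feats)) != len(feats):
                raise ConfigurationError(f"duplicate base feature label in game {game}")

    def all_tasks(self):
        for game in self.game_order:
            for spec in self.tasks[game]:
                yield spec


def _default_tasks() -> dict[str, tuple[TaskSpec, ...]]:
    left = default_layout("left")
    right = default_layout("right")
    forefoot = {"left": tuple(left.sensors_in("met1") + left.sensors_in("met3")
                              + left.sensors_in("met5")),
                "right": tuple(right.sensors_in("met1") + right.sensors_in("met3")
                               + right.sensors_in("met5"))}
    hallux = {"left": left.sensors_in("hallux")[0], "right": right.sensors_in("hallux")[0]}
    heel = {"left": left.sensors_in("heel")[0], "right": right.sensors_in("heel")[0]}

    # AC: 14 apples, feet alternating (odd -> left), carriage on the forefoot.
    ac = tuple(
        TaskSpec(game="AC", task_index=i,
                 controlling_foot="left" if i % 2 == 1 else "right",
                 target_sensors=forefoot["left" if i % 2 == 1 else "right"],
                 target_band=(0.35, 0.65), timeout=8.0, stimulus_onset=0.5)
        for i in range(1, 15))

    # BF: 10 obstacles, altitude from the forefoot pressure differential.
    bf_bands = [(0.20, 0.50), (0.50, 0.80), (0.30, 0.60), (0.40, 0.70), (0.15, 0.45),
                (0.55, 0.85), (0.35, 0.65), (0.25, 0.55), (0.45, 0.75), (0.30, 0.60)]
    bf = tuple(
        TaskSpec(game="BF", task_index=i, controlling_foot="both",
                 target_sensors=forefoot["left"] + forefoot["right"],
                 target_band=bf_bands[i - 1], timeout=8.0, stimulus_onset=0.5)
        for i in range(1, 11))

    # CP: 8 tasks alternating feet; green (low) bands on the heel, yellow
    # (high) bands on the hallux; two of each are deliberately narrow.
    cp_spec = [("left", heel, (0.20, 0.45)), ("right", hallux, (0.55, 0.85)),
               ("left", hallux, (0.60, 0.72)), ("right", heel, (0.25, 0.50)),
               ("left", heel, (0.30, 0.42)), ("right", hallux, (0.50, 0.80)),
               ("left", hallux, (0.55, 0.85)), ("right", heel, (0.22, 0.34))]
    cp = tuple(
        TaskSpec(game="CP", task_index=i, controlling_foot=foot,
                 target_sensors=(sens[foot],), target_band=band,
                 timeout=25.0, stimulus_onset=0.5, hold_duration=3.0)
        for i, (foot, sens, band) in enumerate(cp_spec, start=1))

    # IJ: 10 jumps alternating feet, peak pressure inside the band.
    ij_bands = [(0.30, 0.50), (0.50, 0.70), (0.25, 0.45), (0.55, 0.75), (0.35, 0.55),
                (0.60, 0.80), (0.30, 0.50), (0.45, 0.65), (0.25, 0.45), (0.55, 0.75)]
    ij = tuple(
        TaskSpec(game="IJ", task_index=i,
                 controlling_foot="left" if i % 2 == 1 else "right",
                 target_sensors=(hallux["left" if i % 2 == 1 else "right"],),
                 target_band=ij_bands[i - 1], timeout=12.0, stimulus_onset=0.5)
        for i in range(1, 11))

    return {"AC": ac, "BF": bf, "CP": cp, "IJ": ij}


def build_default_session_config(overrides: Mapping | None = None) -> GameSessionConfig:
    """Build the default session configuration, optionally overriding fields.

    Defaults: game order AC,BF,CP,IJ; 14 AC tasks; 25 s CP timeout; 200 Hz
    sampling; 3.4 mbar quantization in [250, 7000] mbar; 900 s time budget.
    `overrides` may replace any ``GameSessionConfig`` field by name.
    """
    layouts = {"left": default_layout("left"), "right": default_layout("right")}
    cfg = GameSessionConfig(
        game_order=("AC", "BF", "CP", "IJ"),
        tasks=_default_tasks(),
        sensor_layout=layouts,
        calibration=default_calibration(*layouts.values()),
    )
    if overrides:
        unknown = set(overrides) - set(cfg.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = replace(cfg, **dict(overrides))
    return cfg


# ---------------------------------------------------------------------------
# Pressure transforms
# ---------------------------------------------------------------------------

def normalize_pressure(raw, sensor_id: str, calibration: CalibrationProfile):
    """Affine map of raw mbar onto [0, 1] via the sensor's calibration.

    0 at the rest baseline, 1 at the voluntary maximum, clipped outside.
    Accepts scalars or arrays.
    """
    if sensor_id not in calibration.baseline:
        raise KeyError(f"sensor {sensor_id!r} not in calibration profile")
    lo = calibration.baseline[sensor_id]
    hi = calibration.maximum[sensor_id]
    out = np.clip((np.asarray(raw, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return float(out) if np.isscalar(raw) else out


def quantize_pressure(raw):
    """Snap raw mbar onto the 3.4 mbar sensor grid within [250, 7000].

    ``250 + 3.4 * round((clip(raw) - 250) / 3.4)`` with ties-to-even
    rounding; idempotent.  Accepts scalars or arrays.
    """
    clipped = np.clip(np.asarray(raw, dtype=float), PRESSURE_MIN, PRESSURE_MAX)
    out = PRESSURE_MIN + QUANTIZATION_STEP * np.round(
        (clipped - PRESSURE_MIN) / QUANTIZATION_STEP)
    out = np.minimum(out, PRESSURE_MAX)
    return float(out) if np.isscalar(raw) else out


def _mirror_sensor(sensor_id: str) -> str:
    if sensor_id.startswith("L"):
        return "R" + sensor_id[1:]
    if sensor_id.startswith("R"):
        return "L" + sensor_id[1:]
    return sensor_id


def mirror_session_config(config: GameSessionConfig) -> GameSessionConfig:
    """Swap left and right feet everywhere in a session configuration.

    Task indices, bands and timings are preserved; only the controlling foot
    and target sensors flip.  Mirroring permutes TCL/TCR catalogue names but
    preserves the catalogue size.
    """
    foot_swap = {"left": "right", "right": "left", "both": "both"}
    tasks = {
        game: tuple(replace(
            t, controlling_foot=foot_swap[t.controlling_foot],
            target_sensors=tuple(_mirror_sensor(s) for s in t.target_sensors))
            for t in specs)
        for game, specs in config.tasks.items()}
    return replace(config, tasks=tasks)


# ---------------------------------------------------------------------------
# Task combinations and the feature catalogue
# ---------------------------------------------------------------------------

def enumerate_task_combinations(config: GameSessionConfig) -> list[TaskCombination]:
    """Group each game's tasks by controlling foot into TCL/TCR/TCB sets.

    Deterministic order: games in session order, scopes left, right, both.
    Every task belongs to exactly one TC.
    """
    out: list[TaskCombination] = []
    for game in config.game_order:
        by_foot: dict[str, list[int]] = {"left": [], "right": [], "both": []}
        for spec in config.tasks[game]:
            by_foot[spec.controlling_foot].append(spec.task_index)
        for scope, prefix in (("left", "TCL"), ("right", "TCR"), ("both", "TCB")):
            members = by_foot[scope]
            if members:
                out.append(TaskCombination(id=f"{prefix}1", game=game,
                                           member_tasks=tuple(sorted(members)),
                                           foot_scope=scope))
    return out


def enumerate_feature_catalogue(
        config: GameSessionConfig,
        base_features: Mapping[str, Sequence[str]] | None = None,
) -> list[FeatureDescriptor]:
    """Enumerate the full feature catalogue for a session configuration.

    One primary descriptor per (task, base feature) and three secondary
    descriptors (sum, mean, sd) per (task combination, base feature).  Names
    are unique and stable: ``<game>_TS<i>_<base>`` and
    ``<game>_<TCid>_<base>_<agg>``.
    """
    base_features = dict(base_features or config.base_features)
    for game, feats in base_features.items():
        if len(set(feats)) != len(feats):
            raise ConfigurationError(f"duplicate base feature label in game {game}")
        if not feats:
            raise ConfigurationError(f"game {game} needs at least one base feature")
    catalogue: list[FeatureDescriptor] = []
    for game in config.game_order:
        feats = base_features[game]
        for spec in config.tasks[game]:
            for bf in feats:
                catalogue.append(FeatureDescriptor(
                    name=f"{game}_TS{spec.task_index}_{bf}", kind="primary",
                    game=game, source=f"TS{spec.task_index}",
                    base_feature=bf, aggregation="none"))
    tcs = enumerate_task_combinations(config)
    for tc in tcs:
        for bf in base_features[tc.game]:
            for agg in ("sum", "mean", "sd"):
                catalogue.append(FeatureDescriptor(
                    name=f"{tc.game}_{tc.id}_{bf}_{agg}", kind="secondary",
                    game=tc.game, source=tc.id, base_feature=bf, aggregation=agg))
    names = [d.name for d in catalogue]
    assert len(names) == len(set(names)), "catalogue names must be unique"
    return catalogue
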