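"""Simulation of full game sessions from latent participant traits.

Each task produces a pressure trace on its target sensors plus an outcome.
The motor model is a first-order lag toward the target pressure (time
constant ``TAU``) that starts after a trait-dependent reaction latency,
with additive Gaussian control noise.  Impairments enter mechanistically:

* cognitive dysfunction -> longer reaction latency, more decision errors
  (acting on the wrong foot/region costs a recovery delay);
* neuropathy -> noisier pressure control and a higher sensation threshold
  (bands narrower than the threshold are hard to hold -> drift-outs);
* fatigue -> latency drifts upward with task position within the session.

All emitted pressures are quantized to the 3.4 mbar sensor grid (through the
calibration map) and re-normalized, as the real acquisition chain would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .catalogue import (GameSessionConfig, TaskSpec, normalize_pressure,
                        quantize_pressure)
from .cohort import LatentTraits, Participant

#: Motor time constant of the first-order lag controller, s.
TAU = 0.3
#: Time from stimulus onset until an apple reaches the carriage line (AC)
#: or the balloon reaches the obstacle (BF), s.
EVENT_DELAY = 3.0
#: Recovery delay after a decision error (wrong foot/region), s.
DECISION_ERROR_DELAY = 1.0
#: Maximum attempts per island in IJ before the task counts as failure.
IJ_RETRY_CAP = 5
#: Collision tolerance for BF tracking error, normalized pressure units.
BF_COLLISION_TOL = 0.15


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PressureSample:
    t: float
    sensor_id: str
    value: float


@dataclass
class TaskTrace:
    """Sensor trace and outcome of one task.

    ``values`` has one column per entry of ``sensor_ids``, one row per time
    point; ``aux`` carries game-specific scalars used downstream by the
    feature extractor.
    """

    game: str
    task_index: int
    times: np.ndarray
    sensor_ids: tuple[str, ...]
    values: np.ndarray
    outcome: str  # success | failure | timeout
    response_time: float | None
    restarts: int = 0
    aux: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def samples(self) -> Iterator[PressureSample]:
        for i, t in enumerate(self.times):
            for j, sid in enumerate(self.sensor_ids):
                yield PressureSample(float(t), sid, float(self.values[i, j]))


@dataclass
class SessionRecord:
    participant_id: str
    config_hash: str
    traces: list[TaskTrace]
    total_duration: float
    complete: bool


def _quantize_normalized(x: np.ndarray, sensor_id: str,
                         config: GameSessionConfig) -> np.ndarray:
    """Round-trip normalized pressure through the mbar sensor grid."""
    cal = config.calibration
    lo, hi = cal.baseline[sensor_id], cal.maximum[sensor_id]
    raw = lo + np.clip(x, 0.0, 1.0) * (hi - lo)
    return normalize_pressure(quantize_pressure(raw), sensor_id, cal)


def _ou_noise(times: np.ndarray, sd: float, rng: np.random.Generator,
              tcorr: float = 0.5) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck control noise with correlation time tcorr.

    Physiological pressure-control error wanders slowly rather than flipping
    sample-to-sample; the marginal SD equals ``sd`` at any sampling rate.
    """
    if sd <= 0 or len(times) == 0:
        return np.zeros_like(times)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    from scipy.signal import lfilter
    rho = np.exp(-dt / tcorr)
    w = rng.normal(0.0, sd, size=times.shape)
    c = np.sqrt(1.0 - rho * rho)
    out, _ = lfilter([c], [1.0, -rho], w, zi=np.array([(1.0 - c) * w[0]]))
    return out


def _lag(times: np.ndarray, start: float, target: float, x0: float = 0.0) -> np.ndarray:
    """First-order approach from x0 to target beginning at ``start``."""
    out = np.full_like(times, x0, dtype=float)
    active = times >= start
    out[active] = target + (x0 - target) * np.exp(-(times[active] - start) / TAU)
    return out


def _draw_latency(traits: LatentTraits, task_position: int,
                  rng: np.random.Generator) -> tuple[float, bool]:
    lat = traits.reaction_latency_mean + traits.fatigue_slope * task_position
    if traits.reaction_latency_sd > 0:
        lat = rng.normal(lat, traits.reaction_latency_sd)
    err = rng.random() < traits.decision_error_prob
    return max(0.0, float(lat)), bool(err)


def _grid(duration: float, rate: float) -> np.ndarray:
    n = max(2, int(round(duration * rate)) + 1)
    return np.arange(n) / rate


def _finalize(x: np.ndarray, task: TaskSpec, config: GameSessionConfig,
              per_sensor: dict[str, np.ndarray] | None = None) -> np.ndarray:
    cols = []
    for sid in task.target_sensors:
        col = per_sensor[sid] if per_sensor else x
        cols.append(_quantize_normalized(col, sid, config))
    return np.column_stack(cols)


def _simulate_ac(task: TaskSpec, traits: LatentTraits, task_position: int,
                 rng: np.random.Generator, config: GameSessionConfig) -> TaskTrace:
    rate = config.sampling_rate
    catch_time = task.stimulus_onset + EVENT_DELAY
    duration = min(task.timeout, catch_time + 0.5)
    times = _grid(duration, rate)
    latency, err = _draw_latency(traits, task_position, rng)
    start = task.stimulus_onset + latency + (DECISION_ERROR_DELAY if err else 0.0)
    center = task.band_center
    x = _lag(times, start, center) + _ou_noise(times, traits.pressure_noise_sd, rng)
    values = _finalize(np.clip(x, 0.0, 1.0), task, config)
    mean_track = values.mean(axis=1)
    catch_idx = int(np.argmin(np.abs(times - catch_time)))
    positional_error = float(abs(mean_track[catch_idx] - center))
    success = positional_error < task.band_width / 2.0
    after = mean_track[times >= start]
    hi = task.target_band[1]
    overshoots = int(np.sum((after[1:] > hi) & (after[:-1] <= hi)))
    return TaskTrace(
        game="AC", task_index=task.task_index, times=times,
        sensor_ids=task.target_sensors, values=values,
        outcome="success" if success else "failure",
        response_time=latency + (DECISION_ERROR_DELAY if err else 0.0),
        restarts=0,
        aux={"catch_success": float(success), "positional_error": positional_error,
             "overshoot_count": float(overshoots), "catch_time": catch_time,
             "stimulus_onset": task.stimulus_onset})


def _simulate_bf(task: TaskSpec, traits: LatentTraits, task_position: int,
                 rng: np.random.Generator, config: GameSessionConfig) -> TaskTrace:
    rate = config.sampling_rate
    obstacle_time = task.stimulus_onset + EVENT_DELAY
    duration = min(task.timeout, obstacle_time + 0.5)
    times = _grid(duration, rate)
    latency, err = _draw_latency(traits, task_position, rng)
    start = task.stimulus_onset + latency + (DECISION_ERROR_DELAY if err else 0.0)
    center = task.band_center
    # balloon altitude = 0.5 + (meanL - meanR)/2 over the forefoot sensors
    alt = _lag(times, start, center, x0=0.5) + _ou_noise(
        times, traits.pressure_noise_sd, rng)
    alt = np.clip(alt, 0.0, 1.0)
    per_sensor = {}
    for sid in task.target_sensors:
        per_sensor[sid] = alt if sid.startswith("L") else 1.0 - alt
    values = _finalize(alt, task, config, per_sensor=per_sensor)
    left = np.array([sid.startswith("L") for sid in task.target_sensors])
    alt_q = 0.5 + (values[:, left].mean(axis=1) - values[:, ~left].mean(axis=1)) / 2.0
    obs_idx = int(np.argmin(np.abs(times - obstacle_time)))
    tol = min(task.band_width / 2.0, BF_COLLISION_TOL)
    collision = bool(abs(alt_q[obs_idx] - center) > tol)
    track = alt_q[times >= start]
    rmse = float(np.sqrt(np.mean((track - center) ** 2))) if len(track) else np.nan
    return TaskTrace(
        game="BF", task_index=task.task_index, times=times,
        sensor_ids=task.target_sensors, values=values,
        outcome="failure" if collision else "success",
        response_time=latency + (DECISION_ERROR_DELAY if err else 0.0),
        restarts=int(collision),
        aux={"collision_count": float(collision),
             "points_collected": float(not collision),
             "altitude_tracking_rmse": rmse,
             "correction_latency": latency,
             "stimulus_onset": task.stimulus_onset})


def _simulate_cp(task: TaskSpec, traits: LatentTraits, task_position: int,
                 rng: np.random.Generator, config: GameSessionConfig) -> TaskTrace:
    rate = config.sampling_rate
    sid = task.target_sensors[0]
    lo, hi = task.target_band
    width = task.band_width
    if not np.isfinite(traits.sensation_threshold):
        # the band indicator is imperceptible: no response, guaranteed timeout
        times = _grid(task.timeout, rate)
        x = np.clip(rng.normal(0.02, max(traits.pressure_noise_sd, 1e-3),
                               size=times.shape), 0.0, 1.0)
        values = _finalize(x, task, config)
        return TaskTrace(game="CP", task_index=task.task_index, times=times,
                         sensor_ids=task.target_sensors, values=values,
                         outcome="timeout", response_time=None,
                         aux={"timeout_flag": 1.0,
                              "band_exceedance_fraction": 1.0,
                              "band": (lo, hi)})
    latency, err = _draw_latency(traits, task_position, rng)
    start = task.stimulus_onset + latency + (DECISION_ERROR_DELAY if err else 0.0)
    # a band narrower than the sensation threshold cannot be felt reliably:
    # effective control noise grows with the imperceptible remainder
    sd_eff = traits.pressure_noise_sd + 0.5 * max(0.0, traits.sensation_threshold - width)
    times = _grid(task.timeout, rate)
    x = _lag(times, start, task.band_center) + _ou_noise(times, sd_eff, rng)
    values = _finalize(np.clip(x, 0.0, 1.0), task, config)
    xq = values[:, 0]
    in_band = (xq >= lo) & (xq <= hi)
    hold_n = max(1, int(round(task.hold_duration * rate)))
    # first index at which the last hold_n samples were all in band
    run = 0
    hold_end = None
    for i, ok in enumerate(in_band):
        run = run + 1 if ok else 0
        if run >= hold_n:
            hold_end = i
            break
    if hold_end is not None and times[hold_end] <= task.timeout:
        end_idx = min(len(times) - 1, hold_end + int(round(0.3 * rate)))
        hold_start = hold_end - hold_n + 1
        t_hold = float(times[hold_end])
        entry = int(np.argmax(in_band))
        seg = in_band[entry:hold_end + 1]
        exceed = float(1.0 - seg.mean())
        return TaskTrace(
            game="CP", task_index=task.task_index,
            times=times[:end_idx + 1], sensor_ids=task.target_sensors,
            values=values[:end_idx + 1], outcome="success",
            response_time=t_hold,
            aux={"timeout_flag": 0.0, "time_to_valid_hold": t_hold,
                 "hold_window": (hold_start, hold_end),
                 "band_exceedance_fraction": exceed, "band": (lo, hi)})
    exceed = 1.0
    if in_band.any():
        entry = int(np.argmax(in_band))
        exceed = float(1.0 - in_band[entry:].mean())
    return TaskTrace(game="CP", task_index=task.task_index, times=times,
                     sensor_ids=task.target_sensors, values=values,
                     outcome="timeout", response_time=None,
                     aux={"timeout_flag": 1.0,
                          "band_exceedance_fraction": exceed, "band": (lo, hi)})


def _simulate_ij(task: TaskSpec, traits: LatentTraits, task_position: int,
                 rng: np.random.Generator, config: GameSessionConfig) -> TaskTrace:
    rate = config.sampling_rate
    center = task.band_center
    lo, hi = task.target_band
    sd_peak = traits.pressure_noise_sd + 0.25 * min(traits.sensation_threshold, 1.0) \
        if np.isfinite(traits.sensation_threshold) else 1.0
    seg_times: list[np.ndarray] = []
    seg_vals: list[np.ndarray] = []
    t0 = 0.0
    success = False
    attempts = 0
    peak = center
    first_latency = None
    while attempts < IJ_RETRY_CAP:
        latency, err = _draw_latency(traits, task_position, rng)
        if first_latency is None:
            first_latency = latency
        attempts += 1
        peak = center + (rng.normal(0.0, sd_peak) if sd_peak > 0 else 0.0)
        if err:
            peak += 0.25 * (1 if rng.random() < 0.5 else -1)
        peak = float(np.clip(peak, 0.0, 1.0))
        onset = task.stimulus_onset if attempts == 1 else 0.2
        seg_dur = onset + latency + 4 * TAU + 0.4
        if t0 + seg_dur > task.timeout:
            break
        times = _grid(seg_dur, rate)
        start = onset + latency
        x = _lag(times, start, peak)
        fall = times >= start + 4 * TAU
        x[fall] = peak * np.exp(-(times[fall] - (start + 4 * TAU)) / 0.15)
        x = x + _ou_noise(times, traits.pressure_noise_sd * 0.5, rng)
        seg_times.append(times[1:] + t0 if seg_times else times)
        seg_vals.append(x[1:] if len(seg_vals) else x)
        t0 += float(times[-1])
        peak_q = float(_quantize_normalized(np.array([peak]),
                                            task.target_sensors[0], config)[0])
        if lo <= peak_q <= hi:
            success = True
            peak = peak_q
            break
        peak = peak_q
    if not seg_times:  # timeout before any attempt fit in the window
        times = _grid(task.timeout, rate)
        values = _finalize(np.zeros_like(times), task, config)
        return TaskTrace(game="IJ", task_index=task.task_index, times=times,
                         sensor_ids=task.target_sensors, values=values,
                         outcome="timeout", response_time=None,
                         restarts=attempts,
                         aux={"jump_success": 0.0, "attempts": float(attempts)})
    times = np.concatenate(seg_times)
    x = np.clip(np.concatenate(seg_vals), 0.0, 1.0)
    values = _finalize(x, task, config)
    # rise time of the final attempt: 10% -> 90% of peak on the trace
    xq = values[:, 0]
    rise_time = np.nan
    if peak > 0:
        above10 = np.flatnonzero(xq >= 0.1 * peak)
        above90 = np.flatnonzero(xq >= 0.9 * peak)
        if len(above10) and len(above90):
            rise_time = float(times[above90[0]] - times[above10[0]])
    aux = {"jump_success": float(success), "attempts": float(attempts),
           "peak_pressure_error": float(abs(peak - center)),
           "pressure_rise_time": rise_time}
    if success:
        aux["attempts_to_success"] = float(attempts)
    return TaskTrace(game="IJ", task_index=task.task_index, times=times,
                     sensor_ids=task.target_sensors, values=values,
                     outcome="success" if success else "failure",
                     response_time=first_latency, restarts=attempts - 1, aux=aux)


_SIMULATORS = {"AC": _simulate_ac, "BF": _simulate_bf,
               "CP": _simulate_cp, "IJ": _simulate_ij}


def simulate_task(task: TaskSpec, traits: LatentTraits, task_position: int,
                  rng: np.random.Generator,
                  config: GameSessionConfig | None = None) -> TaskTrace:
    """Simulate one task for a participant with the given latent traits.

    ``task_position`` is the 0-based position within the whole session and
    drives the fatigue drift.
    """
    from .catalogue import build_default_session_config
    cfg = config or build_default_session_config()
    return _SIMULATORS[task.game](task, traits, task_position, rng, cfg)


def config_hash(config: GameSessionConfig) -> str:
    import hashlib
    key = repr((config.game_order, tuple(
        (g, tuple((t.task_index, t.controlling_foot, t.target_band, t.timeout,
                   t.hold_duration) for t in config.tasks[g]))
        for g in config.game_order), config.sampling_rate,
        config.session_time_budget))
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def simulate_session(config: GameSessionConfig, participant: Participant,
                     rng: np.random.Generator) -> SessionRecord:
    """Simulate the participant's full four-game session.

    Tasks run in configured order; the session stops once the time budget is
    exhausted (remaining tasks absent, ``complete=False``).  Deterministic
    for a fixed generator state.
    """
    if participant.latent is None:
        raise SimulationError(f"participant {participant.id} has no latent traits")
    traces: list[TaskTrace] = []
    elapsed = 0.0
    complete = True
    position = 0
    for task in config.all_tasks():
        if elapsed >= config.session_time_budget:
            complete = False
            break
        trace = simulate_task(task, participant.latent, position, rng, config)
        traces.append(trace)
        elapsed += trace.duration
        position += 1
    if elapsed > config.session_time_budget:
        complete = False
    return SessionRecord(participant_id=participant.id,
                         config_hash=config_hash(config),
                         traces=traces, total_duration=elapsed,
                         complete=complete)


def validate_session(record: SessionRecord,
                     config: GameSessionConfig) -> list[str]:
    """Return exclusion reasons for a session; an empty list means valid."""
    reasons: list[str] = []
    have = {(t.game, t.task_index) for t in record.traces}
    for game in config.game_order:
        missing = [t.task_index for t in config.tasks[game]
                   if (game, t.task_index) not in have]
        if missing:
            reasons.append(f"incomplete: {game}")
    if not record.complete and not any(r.startswith("incomplete") for r in reasons):
        reasons.append("incomplete: session flagged incomplete")
    for t in record.traces:
        if len(t.times) > 1 and not np.all(np.diff(t.times) > 0):
            reasons.append(f"non-monotone timestamps: {t.game} TS{t.task_index}")
        if len(t.values) and (np.nanmin(t.values) < 0 or np.nanmax(t.values) > 1):
            reasons.append("pressure out of range")
    return reasons


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def session_to_dict(record: SessionRecord, include_samples: bool = True) -> dict:
    tasks = []
    for t in record.traces:
        d = {"game": t.game, "index": t.task_index, "outcome": t.outcome,
             "response_time": t.response_time, "restarts": t.restarts,
             "sensors": list(t.sensor_ids),
             "aux": {k: (list(v) if isinstance(v, tuple) else
                         (None if isinstance(v, float) and np.isnan(v) else v))
                     for k, v in t.aux.items()}}
        if include_samples:
            d["times"] = [round(float(x), 6) for x in t.times]
            d["values"] = [[round(float(v), 6) for v in row] for row in t.values]
        tasks.append(d)
    return {"participant_id": record.participant_id,
            "config_hash": record.config_hash, "tasks": tasks,
            "total_duration": round(record.total_duration, 6),
            "complete": record.complete}


def session_from_dict(d: dict) -> SessionRecord:
    traces = []
    for t in d["tasks"]:
        times = np.asarray(t.get("times", []), dtype=float)
        values = np.asarray(t.get("values", []), dtype=float)
        if values.size == 0:
            values = values.reshape(0, len(t["sensors"]))
        aux = {k: (tuple(v) if isinstance(v, list) else
                   (np.nan if v is None else v)) for k, v in t["aux"].items()}
        traces.append(TaskTrace(game=t["game"], task_index=t["index"],
                                times=times, sensor_ids=tuple(t["sensors"]),
                                values=values, outcome=t["outcome"],
                                response_time=t["response_time"],
                                restarts=t["restarts"], aux=aux))
    return SessionRecord(participant_id=d["participant_id"],
                         config_hash=d["config_hash"], traces=traces,
                         total_duration=d["total_duration"],
                         complete=d["complete"])
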