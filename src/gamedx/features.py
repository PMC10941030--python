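"""Primary and secondary game-feature extraction.

Primary features are computed per task from its trace (e.g. reaction time =
first crossing of a normalized-pressure threshold after stimulus onset).
Secondary features are the sum, mean, and sample SD of a primary feature
over the member tasks of a task combination.  The participant x feature
matrix appends the six individual-risk-profile (IRP) columns: gender, age,
weight, bmi, diabetes_type, diabetes_duration.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import (ConfigurationError, GameSessionConfig, TaskCombination,
                        TaskSpec, enumerate_feature_catalogue,
                        enumerate_task_combinations)
from .simulator import SessionRecord, TaskTrace, validate_session

#: Normalized-pressure threshold defining a detectable reaction.
REACTION_THRESHOLD = 0.2

IRP_COLUMNS = ("gender", "age", "weight", "bmi", "diabetes_type",
               "diabetes_duration")

_MISSING = float("nan")


def _mean_track(trace: TaskTrace) -> np.ndarray:
    return trace.values.mean(axis=1) if trace.values.size else np.empty(0)


def _reaction_time(trace: TaskTrace, task: TaskSpec,
                   threshold: float) -> float:
    if trace.outcome == "timeout":
        return _MISSING
    onset = task.stimulus_onset
    after = trace.times >= onset
    crossed = (trace.values.max(axis=1) >= threshold) & after
    idx = np.flatnonzero(crossed)
    if len(idx) == 0:
        return _MISSING
    return float(trace.times[idx[0]] - onset)


def _overshoot_count(trace: TaskTrace, task: TaskSpec) -> float:
    x = _mean_track(trace)
    after = trace.times >= task.stimulus_onset
    x = x[after]
    hi = task.target_band[1]
    if len(x) < 2:
        return 0.0
    return float(np.sum((x[1:] > hi) & (x[:-1] <= hi)))


def _altitude_rmse(trace: TaskTrace, task: TaskSpec) -> float:
    left = np.array([s.startswith("L") for s in trace.sensor_ids])
    if not left.any() or left.all():
        return _MISSING
    alt = 0.5 + (trace.values[:, left].mean(axis=1)
                 - trace.values[:, ~left].mean(axis=1)) / 2.0
    start = trace.response_time
    sel = trace.times >= (task.stimulus_onset + (start or 0.0))
    if not sel.any():
        return _MISSING
    return float(np.sqrt(np.mean((alt[sel] - task.band_center) ** 2)))


def _hold_stability_sd(trace: TaskTrace) -> float:
    window = trace.aux.get("hold_window")
    if window is None:
        return _MISSING
    i0, i1 = int(window[0]), int(window[1])
    seg = trace.values[i0:i1 + 1, 0]
    if len(seg) < 2:
        return _MISSING
    return float(np.std(seg, ddof=1))


def extract_primary(trace: TaskTrace, task: TaskSpec,
                    base_features: Sequence[str],
                    threshold: float = REACTION_THRESHOLD) -> dict[str, float]:
    """Compute the requested primary features for one task trace.

    Values undefined for the trace (e.g. reaction time on a timeout) are
    returned as NaN.
    """
    out: dict[str, float] = {}
    for bf in base_features:
        if bf == "reaction_time":
            v = _reaction_time(trace, task, threshold)
        elif bf == "overshoot_count":
            v = _overshoot_count(trace, task)
        elif bf == "altitude_tracking_rmse":
            v = _altitude_rmse(trace, task)
        elif bf == "hold_stability_sd":
            v = _hold_stability_sd(trace)
        elif bf == "timeout_flag":
            v = float(trace.outcome == "timeout")
        elif bf == "correction_latency":
            v = trace.aux.get("correction_latency",
                              trace.response_time if trace.response_time is not None
                              else _MISSING)
        elif bf in ("catch_success", "positional_error", "collision_count",
                    "points_collected", "time_to_valid_hold",
                    "band_exceedance_fraction", "attempts_to_success",
                    "peak_pressure_error", "jump_success", "pressure_rise_time"):
            v = trace.aux.get(bf, _MISSING)
        else:
            raise ConfigurationError(f"unknown base feature {bf!r}")
        out[bf] = float(v) if v is not None else _MISSING
    return out


def aggregate_secondary(primaries: Mapping[int, Mapping[str, float]],
                        tc: TaskCombination,
                        base_feature: str) -> tuple[float, float, float]:
    """(sum, mean, sample SD) of a primary feature over a TC's member tasks.

    Aggregates over non-missing member values; all three are NaN when no
    value is present, the SD when fewer than two are.
    """
    vals = np.array([primaries[t].get(base_feature, _MISSING)
                     for t in tc.member_tasks if t in primaries], dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return _MISSING, _MISSING, _MISSING
    s, m = float(vals.sum()), float(vals.mean())
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else _MISSING
    return s, m, sd


def extract_session_features(record: SessionRecord, config: GameSessionConfig,
                             threshold: float = REACTION_THRESHOLD) -> dict[str, float]:
    """Full catalogue feature vector (name -> value) for one session."""
    task_specs = {(t.game, t.task_index): t for t in config.all_tasks()}
    per_task: dict[str, dict[int, dict[str, float]]] = {g: {} for g in config.tasks}
    for trace in record.traces:
        spec = task_specs[(trace.game, trace.task_index)]
        per_task[trace.game][trace.task_index] = extract_primary(
            trace, spec, config.base_features[trace.game], threshold)
    out: dict[str, float] = {}
    for game, tasks in per_task.items():
        for idx, feats in tasks.items():
            for bf, v in feats.items():
                out[f"{game}_TS{idx}_{bf}"] = v
    for tc in enumerate_task_combinations(config):
        for bf in config.base_features[tc.game]:
            s, m, sd = aggregate_secondary(per_task[tc.game], tc, bf)
            out[f"{tc.game}_{tc.id}_{bf}_sum"] = s
            out[f"{tc.game}_{tc.id}_{bf}_mean"] = m
            out[f"{tc.game}_{tc.id}_{bf}_sd"] = sd
    return out


def build_feature_matrix(records: Sequence[SessionRecord],
                         cohort: pd.DataFrame,
                         config: GameSessionConfig,
                         validate: bool = True) -> pd.DataFrame:
    """Participants x features table over valid, complete sessions.

    Columns are the full catalogue (deterministic order) followed by the six
    IRP columns; rows are indexed by participant id.  Sessions failing
    :func:`gamedx.simulator.validate_session` are excluded.
    """
    catalogue = [d.name for d in enumerate_feature_catalogue(config)]
    cohort_idx = cohort.set_index("id")
    rows, ids = [], []
    for rec in records:
        if validate and validate_session(rec, config):
            continue
        if rec.participant_id not in cohort_idx.index:
            raise KeyError(
                f"participant {rec.participant_id} absent from cohort table")
        feats = extract_session_features(rec, config)
        crow = cohort_idx.loc[rec.participant_id]
        row = [feats.get(name, _MISSING) for name in catalogue]
        row += [1.0 if crow["gender"] == "male" else 0.0,
                float(crow["age"]), float(crow["weight"]), float(crow["bmi"]),
                float(crow["diabetes_type"]), float(crow["diabetes_duration"])]
        rows.append(row)
        ids.append(rec.participant_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"),
                        columns=list(catalogue) + list(IRP_COLUMNS))


def preprocess_features(matrix: pd.DataFrame,
                        missing_threshold: float = 0.2
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop constant / mostly-missing columns, median-impute the rest.

    Columns missing in more than ``missing_threshold`` of rows and columns
    constant over their observed values are dropped (IRP columns are always
    kept).  Returns the cleaned matrix and a manifest of dropped columns.
    """
    dropped: list[tuple[str, str]] = []
    keep: dict[str, pd.Series] = {}
    for col in matrix.columns:
        s = matrix[col].astype(float)
        if col in IRP_COLUMNS:
            keep[col] = s.fillna(s.median())
            continue
        frac_missing = s.isna().mean()
        if frac_missing > missing_threshold:
            dropped.append((col, f"missing in {frac_missing:.0%} of rows"))
            continue
        obs = s.dropna()
        if len(obs) == 0 or obs.nunique() <= 1:
            dropped.append((col, "constant"))
            continue
        keep[col] = s.fillna(obs.median())
    manifest = pd.DataFrame(dropped, columns=["column", "reason"])
    return pd.DataFrame(keep, index=matrix.index), manifest
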