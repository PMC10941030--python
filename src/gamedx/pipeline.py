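"""End-to-end orchestration: cohort -> sessions -> features -> analyses.

A single master seed fans out into per-stage seeds through
``numpy.random.SeedSequence`` spawning in a fixed stage order, so each stage
is individually reproducible.  Artifacts are plain CSV/JSON/Markdown files
listed in the run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import (DEFAULT_COVARIATES, ExposureSpec, MatchResult,
                          MatchSpec, association_analysis, cardinality_match)
from .catalogue import GameSessionConfig, build_default_session_config
from .classify import CONTRAST_GROUPS, ModelSpec, run_contrast
from .cohort import CohortConfig, cohort_to_frame, latents_to_frame, sample_cohort
from .features import build_feature_matrix, preprocess_features
from .simulator import session_to_dict, simulate_session, validate_session
from .stats import compare_groups, holm_adjust, prevalence, summarize_cohort

log = logging.getLogger("gamedx")

_STAGES = ("cohort", "sessions", "features", "stats", "matching", "classify",
           "screen")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


@dataclass
class RunManifest:
    seed: int
    stage_seeds: dict[str, int]
    config_hash: str
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def simulate_study(seed: int, cohort_config: CohortConfig | None = None,
                   session_config: GameSessionConfig | None = None
                   ) -> tuple[pd.DataFrame, list, pd.DataFrame, GameSessionConfig]:
    """Cohort + sessions + preprocessed feature matrix for one seed.

    Returns (cohort table, session records, preprocessed feature matrix,
    session config).  The session config defaults to the standard games at a
    50 Hz simulation rate (features are sampling-rate-invariant by
    construction).
    """
    seeds = stage_seeds(seed)
    ccfg = cohort_config or CohortConfig(seed=seeds["cohort"])
    participants = sample_cohort(ccfg)
    cohort = cohort_to_frame(participants)
    scfg = session_config or build_default_session_config({"sampling_rate": 50.0})
    rng = np.random.default_rng(seeds["sessions"])
    records = [simulate_session(scfg, p, rng) for p in participants]
    matrix = build_feature_matrix(records, cohort, scfg)
    matrix, _ = preprocess_features(matrix)
    return cohort, records, matrix, scfg


def feature_group_screen(matrix: pd.DataFrame, cohort: pd.DataFrame,
                         alpha: float = 0.05,
                         match_spec: MatchSpec | None = None) -> dict:
    """Per-contrast lists of game features that differ from the reference.

    For each impaired group a covariate-matched subcohort against the
    unimpaired reference is built (cardinality matching), then every game
    feature is compared between the two groups with the normality-gated test
    and Holm-adjusted within the subcohort.  Constant features are excluded
    before testing.
    """
    from .features import IRP_COLUMNS
    out = {}
    groups = cohort.set_index("id")["group"]
    for contrast, positive in CONTRAST_GROUPS.items():
        ids = [i for i in matrix.index
               if groups.get(i) in ("-PNP-CD", positive)]
        sub_cohort = cohort[cohort["id"].isin(ids)].copy()
        sub_cohort["is_positive"] = sub_cohort["group"] == positive
        match = cardinality_match(sub_cohort, "is_positive",
                                  match_spec or MatchSpec())
        keep = set(match.retained_ids["False"]) | set(match.retained_ids["True"])
        keep &= set(matrix.index)
        sub = matrix.loc[sorted(keep)]
        labels = groups.loc[sub.index] == positive
        feats, pvals, tests = [], [], []
        for col in sub.columns:
            if col in IRP_COLUMNS or sub[col].nunique() <= 1:
                continue
            res = compare_groups(sub[col], labels, "continuous", variable=col)
            feats.append(col)
            pvals.append(res.p_value)
            tests.append(res.test_name)
        adjusted = holm_adjust(pvals)
        table = pd.DataFrame({"feature": feats, "test": tests,
                              "p_value": pvals, "adjusted_p": adjusted})
        sig = table[table["adjusted_p"] < alpha].sort_values("adjusted_p")
        out[contrast] = {"significant": sig.reset_index(drop=True),
                         "all": table, "matched_n": match.n_per_group,
                         "match_status": match.status}
    return out


def run_all(out_dir: str | Path, seed: int = 0,
            cohort_config: CohortConfig | None = None,
            session_config: GameSessionConfig | None = None,
            models: list[ModelSpec] | None = None,
            folds: int = 10, repeats: int = 10,
            write_sessions: bool = False) -> RunManifest:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)

    def _stage(name):
        log.info("stage %s (seed %d)", name, seeds.get(name, seed))

    try:
        _stage("cohort")
        ccfg = cohort_config or CohortConfig(seed=seeds["cohort"])
        participants = sample_cohort(ccfg)
        cohort = cohort_to_frame(participants)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        latents_to_frame(participants).to_csv(out_dir / "latents.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage cohort failed: {exc}") from exc

    try:
        _stage("sessions")
        scfg = session_config or build_default_session_config(
            {"sampling_rate": 50.0})
        rng = np.random.default_rng(seeds["sessions"])
        records = [simulate_session(scfg, p, rng) for p in participants]
        n_valid = sum(1 for r in records if not validate_session(r, scfg))
        if write_sessions:
            sess_dir = out_dir / "sessions"
            sess_dir.mkdir(exist_ok=True)
            for r in records:
                with open(sess_dir / f"{r.participant_id}.json", "w") as fh:
                    json.dump(session_to_dict(r), fh)
        log.info("sessions: %d simulated, %d valid", len(records), n_valid)
    except Exception as exc:
        raise RuntimeError(f"stage sessions failed: {exc}") from exc

    try:
        _stage("features")
        matrix = build_feature_matrix(records, cohort, scfg)
        matrix, manifest_df = preprocess_features(matrix)
        matrix.to_csv(out_dir / "features.csv")
        manifest_df.to_csv(out_dir / "dropped_columns.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage features failed: {exc}") from exc

    try:
        _stage("stats")
        table1 = summarize_cohort(cohort, "group")
        table1.to_csv(out_dir / "table1.csv", index=False)
        n_pnp, p_pnp = prevalence(cohort["pnp_label"])
        n_cd, p_cd = prevalence(cohort["cd_label"])
        n_both, p_both = prevalence(cohort["pnp_label"] & cohort["cd_label"])
        with open(out_dir / "prevalence.json", "w") as fh:
            json.dump({"pnp": {"n": n_pnp, "pct": round(100 * p_pnp, 1)},
                       "cd": {"n": n_cd, "pct": round(100 * p_cd, 1)},
                       "both": {"n": n_both, "pct": round(100 * p_both, 1)}},
                      fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage stats failed: {exc}") from exc

    try:
        _stage("matching")
        match = cardinality_match(cohort, "cd_label", MatchSpec())
        with open(out_dir / "match.json", "w") as fh:
            json.dump({"retained": match.retained_ids,
                       "smd_before": match.smd_before,
                       "smd_after": match.smd_after,
                       "status": match.status}, fh, indent=2)
        table3 = association_analysis(
            cohort, ExposureSpec("pnp_label", "cd_label", DEFAULT_COVARIATES),
            matched=match)
        table3.to_csv(out_dir / "table3.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage matching failed: {exc}") from exc

    try:
        _stage("classify")
        contrasts = {}
        for contrast in CONTRAST_GROUPS:
            res = run_contrast(matrix, cohort, contrast, models=models,
                               folds=folds, repeats=repeats,
                               seed=seeds["classify"])
            contrasts[contrast] = res
            res["table"].to_csv(out_dir / f"classification_{contrast}.csv",
                                index=False)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    try:
        _stage("screen")
        screen = feature_group_screen(matrix, cohort)
        for contrast, res in screen.items():
            res["significant"].to_csv(
                out_dir / f"screen_{contrast}.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage screen failed: {exc}") from exc

    from .simulator import config_hash
    manifest = RunManifest(
        seed=seed, stage_seeds=seeds, config_hash=config_hash(scfg),
        outputs={p.name: str(p) for p in sorted(out_dir.glob("*.*"))},
        counts={"participants": len(participants),
                "valid_sessions": n_valid,
                "features_retained": matrix.shape[1],
                "matched_per_group": match.n_per_group})
    with open(out_dir / "manifest.json", "w") as fh:
        fh.write(manifest.to_json())
    return manifest
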