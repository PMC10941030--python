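"""Synthetic cohort generation for the four diabetes impairment groups.

Participants are patients with diabetes aged over 50, split into four groups
by the presence of peripheral neuropathy (PNP) and cognitive dysfunction
(CD): -PNP-CD, +PNP-CD, -PNP+CD, +PNP+CD.  The generator reproduces the
published cohort structure — group sizes 80/92/28/61 (n=261), per-group
covariate marginals (median/IQR moment-matched), and clinical scores (NDS,
NSS, MoCA) that are rejection-sampled so the diagnostic rules reproduce each
participant's group label exactly.

Diagnostic rules:

* PNP  iff  NDS >= 6, or NDS >= 3 and NSS >= 5.
* CD   iff  education-adjusted MoCA < 26, where one point is added for
  participants with 12 or fewer years of education (capped at 30).

Latent traits (reaction latency, pressure-control noise, sensation
threshold, decision-error probability, fatigue drift) are a mechanistic
stand-in for the capabilities the games probe; they drive the session
simulator and are linked to the clinical scores through shared latent
cognition / neuropathy variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("-PNP-CD", "+PNP-CD", "-PNP+CD", "+PNP+CD")
#: Published group sizes for n=261.
DEFAULT_GROUP_COUNTS = (80, 92, 28, 61)

#: Per-group covariate marginals: median (IQR) for continuous variables,
#: proportions for binary ones, in group order -PNP-CD, +PNP-CD, -PNP+CD, +PNP+CD.
GROUP_MARGINALS = {
    "age": [(65.0, 11.0), (69.0, 9.0), (68.5, 13.5), (71.0, 9.0)],
    "weight": [(85.5, 20.2), (88.0, 20.0), (84.5, 18.2), (87.0, 24.0)],
    "bmi": [(28.2, 7.3), (29.5, 7.1), (26.9, 5.0), (29.6, 7.3)],
    "diabetes_duration": [(10.0, 11.2), (18.0, 21.0), (10.0, 18.2), (16.0, 12.0)],
    "female_prob": [0.462, 0.348, 0.214, 0.311],
    "type1_prob": [0.212, 0.261, 0.071, 0.131],
}

_NORMAL_IQR = 1.3489795  # IQR of the standard normal


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a group label."""


class ValidationError(ValueError):
    """Raised for out-of-range clinical scores."""


@dataclass(frozen=True)
class LatentTraits:
    cognition: float  # higher = better
    neuropathy: float  # higher = worse
    reaction_latency_mean: float  # s
    reaction_latency_sd: float  # s
    pressure_noise_sd: float  # normalized pressure units
    sensation_threshold: float  # normalized pressure units
    decision_error_prob: float
    fatigue_slope: float  # latency increment per task position, s

    def __post_init__(self) -> None:
        if self.reaction_latency_sd < 0 or self.pressure_noise_sd < 0:
            raise ValidationError("dispersion parameters must be >= 0")
        if not 0.0 <= self.decision_error_prob <= 1.0:
            raise ValidationError("decision_error_prob must lie in [0, 1]")


#: Noiseless, instantaneous "ideal player" used in limit tests.
PERFECT_TRAITS = LatentTraits(
    cognition=3.0, neuropathy=-3.0, reaction_latency_mean=0.0,
    reaction_latency_sd=0.0, pressure_noise_sd=0.0, sensation_threshold=0.0,
    decision_error_prob=0.0, fatigue_slope=0.0)


@dataclass(frozen=True)
class Participant:
    id: str
    gender: str  # female | male
    age: float
    weight: float
    bmi: float
    diabetes_type: int  # 1 | 2
    diabetes_duration: float
    education_years: int
    nds: int
    nss: int
    moca_raw: int
    pnp_label: bool
    cd_label: bool
    latent: LatentTraits | None = None

    @property
    def group(self) -> str:
        return f"{'+' if self.pnp_label else '-'}PNP{'+' if self.cd_label else '-'}CD"


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the study conditions."""

    n_total: int = 261
    group_counts: tuple[int, int, int, int] = DEFAULT_GROUP_COUNTS
    # Impairment effect sizes on the latent traits.
    beta_cd_latency: float = 0.25  # s added to mean reaction latency
    beta_cd_error: float = 0.10  # added decision-error probability
    beta_pnp_noise: float = 0.04  # added pressure-control noise SD
    beta_pnp_threshold: float = 0.10  # added sensation threshold
    low_education_prob: float = 0.6  # P(education <= 12 years)
    retry_cap: int = 1000
    seed: int = 0
    marginals: dict = field(default_factory=lambda: {
        k: list(v) for k, v in GROUP_MARGINALS.items()})

    def __post_init__(self) -> None:
        if sum(self.group_counts) != self.n_total:
            raise ValueError(
                f"group_counts {self.group_counts} sum to {sum(self.group_counts)}, "
                f"not n_total={self.n_total}")
        for name in ("beta_cd_latency", "beta_cd_error",
                     "beta_pnp_noise", "beta_pnp_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Diagnostic rules
# ---------------------------------------------------------------------------

def diagnose_pnp(nds: int, nss: int) -> bool:
    """PNP iff NDS>=6, or NDS>=3 combined with NSS>=5."""
    if not (0 <= nds <= 10 and 0 <= nss <= 10):
        raise ValidationError(f"NDS/NSS must lie in [0, 10], got ({nds}, {nss})")
    return nds >= 6 or (nds >= 3 and nss >= 5)


def diagnose_cd(moca_raw: int, education_years: float) -> bool:
    """CD iff education-adjusted MoCA < 26 (+1 point if education <= 12 y)."""
    if not 0 <= moca_raw <= 30:
        raise ValidationError(f"MoCA must lie in [0, 30], got {moca_raw}")
    adjusted = min(30, moca_raw + 1) if education_years <= 12 else moca_raw
    return adjusted < 26


_SEVERITY_BANDS = {
    "NDS": ((0, 2, "normal"), (3, 5, "mild"), (6, 8, "moderate"), (9, 10, "severe")),
    "NSS": ((0, 2, "normal"), (3, 4, "mild"), (5, 6, "moderate"), (7, 10, "severe")),
}


def classify_severity(score: int, scale: str) -> str:
    """Band an NDS or NSS score: NDS 3-5/6-8/9-10, NSS 3-4/5-6/7-10."""
    if scale not in _SEVERITY_BANDS:
        raise ValidationError(f"scale must be NDS or NSS, got {scale!r}")
    if not 0 <= score <= 10:
        raise ValidationError(f"{scale} must lie in [0, 10], got {score}")
    for lo, hi, label in _SEVERITY_BANDS[scale]:
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def moment_match_normal(median: float, iqr: float) -> tuple[float, float]:
    """(mean, sd) of a normal with the given median and IQR."""
    return median, iqr / _NORMAL_IQR


def moment_match_lognormal(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    IQR of lognormal(mu, sigma) = 2 * median * sinh(0.6745 * sigma).
    """
    sigma = np.arcsinh(iqr / (2.0 * median)) / (_NORMAL_IQR / 2.0)
    return float(np.log(median)), float(sigma)


def _sample_latents(pnp: bool, cd: bool, cfg: CohortConfig,
                    rng: np.random.Generator) -> LatentTraits:
    u_c = rng.normal()
    u_n = rng.normal()
    cognition = (0.0 if cd else 1.6) + 0.8 * u_c
    neuropathy = (1.6 if pnp else 0.0) + 0.8 * u_n
    return LatentTraits(
        cognition=cognition,
        neuropathy=neuropathy,
        reaction_latency_mean=float(np.clip(
            0.50 + cfg.beta_cd_latency * cd - 0.08 * u_c, 0.05, 3.0)),
        reaction_latency_sd=0.08 + 0.04 * cd,
        pressure_noise_sd=float(np.clip(
            0.020 + cfg.beta_pnp_noise * pnp + 0.010 * u_n, 0.003, 0.5)),
        sensation_threshold=float(np.clip(
            0.05 + cfg.beta_pnp_threshold * pnp + 0.02 * u_n, 0.0, 1.0)),
        decision_error_prob=float(np.clip(
            0.03 + cfg.beta_cd_error * cd - 0.02 * u_c, 0.0, 0.6)),
        fatigue_slope=float(np.clip(
            0.004 + 0.004 * (pnp + cd) + 0.002 * rng.normal(), 0.0, 0.05)),
    )


def assign_clinical_scores(latent: LatentTraits, group: str,
                           rng: np.random.Generator,
                           low_education_prob: float = 0.6,
                           retry_cap: int = 1000) -> tuple[int, int, int, int]:
    """Draw (nds, nss, moca_raw, education_years) consistent with the group.

    Scores are drawn around latent-trait-linked means and rejection-sampled
    until ``diagnose_pnp`` / ``diagnose_cd`` reproduce the group label.
    """
    pnp = group.startswith("+PNP")
    cd = group.endswith("+CD")
    if rng.random() < low_education_prob:
        education = int(rng.integers(8, 13))  # <= 12 years
    else:
        education = int(rng.integers(13, 18))

    nds_mean = 2.0 + 2.2 * latent.neuropathy
    nss_mean = 2.5 + 2.2 * latent.neuropathy
    # keep the sampling window compatible with the target label so the
    # rejection loop terminates even for extreme latent draws
    if pnp:
        nds_mean = min(max(nds_mean, 5.0), 9.0)
        nss_mean = min(max(nss_mean, 5.0), 9.0)
    else:
        nds_mean = min(nds_mean, 2.5)
        nss_mean = min(nss_mean, 3.5)
    for _ in range(retry_cap):
        nds = int(np.clip(round(rng.normal(nds_mean, 1.5)), 0, 10))
        nss = int(np.clip(round(rng.normal(nss_mean, 2.0)), 0, 10))
        if diagnose_pnp(nds, nss) == pnp:
            break
    else:
        raise GenerationError(f"could not realize PNP label for group {group}")

    moca_mean = 26.5 + 1.2 * latent.cognition
    moca_mean = min(max(moca_mean, 22.0), 24.5) if cd else max(min(moca_mean, 29.0), 26.5)
    for _ in range(retry_cap):
        moca = int(np.clip(round(rng.normal(moca_mean, 1.5)), 0, 30))
        if diagnose_cd(moca, education) == cd:
            break
    else:
        raise GenerationError(f"could not realize CD label for group {group}")
    return nds, nss, moca, education


def sample_cohort(config: CohortConfig | None = None) -> list[Participant]:
    """Generate the synthetic cohort with exact per-group quotas.

    Reproducible for a fixed ``config.seed``; covariates follow the
    per-group moment-matched marginals, latent traits carry the configured
    impairment effects, and clinical scores are label-consistent.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    participants: list[Participant] = []
    pid = 0
    for g_idx, group in enumerate(GROUPS):
        pnp = group.startswith("+PNP")
        cd = group.endswith("+CD")
        m = cfg.marginals
        age_mu, age_sd = moment_match_normal(*m["age"][g_idx])
        w_mu, w_sd = moment_match_normal(*m["weight"][g_idx])
        bmi_mu, bmi_sd = moment_match_normal(*m["bmi"][g_idx])
        dur_mu, dur_sigma = moment_match_lognormal(*m["diabetes_duration"][g_idx])
        for _ in range(cfg.group_counts[g_idx]):
            pid += 1
            # age is truncated above 50 ("aged above 50 years")
            age = float(rng.normal(age_mu, age_sd))
            while age <= 50.0:
                age = float(rng.normal(age_mu, age_sd))
            latent = _sample_latents(pnp, cd, cfg, rng)
            nds, nss, moca, edu = assign_clinical_scores(
                latent, group, rng, cfg.low_education_prob, cfg.retry_cap)
            participants.append(Participant(
                id=f"P{pid:04d}",
                gender="female" if rng.random() < m["female_prob"][g_idx] else "male",
                age=round(age, 1),
                weight=round(max(40.0, rng.normal(w_mu, w_sd)), 1),
                bmi=round(max(16.0, rng.normal(bmi_mu, bmi_sd)), 1),
                diabetes_type=1 if rng.random() < m["type1_prob"][g_idx] else 2,
                diabetes_duration=round(min(60.0, float(
                    rng.lognormal(dur_mu, dur_sigma))), 1),
                education_years=edu,
                nds=nds, nss=nss, moca_raw=moca,
                pnp_label=pnp, cd_label=cd, latent=latent))
    return participants


def cohort_to_frame(participants: list[Participant]) -> pd.DataFrame:
    """Cohort table: one row per participant, Participant fields as columns."""
    rows = []
    for p in participants:
        rows.append({
            "id": p.id, "gender": p.gender, "age": p.age, "weight": p.weight,
            "bmi": p.bmi, "diabetes_type": p.diabetes_type,
            "diabetes_duration": p.diabetes_duration,
            "education_years": p.education_years, "nds": p.nds, "nss": p.nss,
            "moca_raw": p.moca_raw, "pnp_label": p.pnp_label,
            "cd_label": p.cd_label, "group": p.group})
    return pd.DataFrame(rows)


def latents_to_frame(participants: list[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        if p.latent is None:
            continue
        d = {"id": p.id}
        d.update({k: getattr(p.latent, k) for k in (
            "cognition", "neuropathy", "reaction_latency_mean",
            "reaction_latency_sd", "pressure_noise_sd", "sensation_threshold",
            "decision_error_prob", "fatigue_slope")})
        rows.append(d)
    return pd.DataFrame(rows)
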