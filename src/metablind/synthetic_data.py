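"""Synthetic trial sets with known ground truth.

The generator emulates placebo-controlled PDE-5 inhibitor trials on the
IIEF-EF change scale: per-trial true arm means are

    theta_arm,i = mu_arm + delta_arm * 1[inadequately blinded]
                  + sum_m beta_m x_m,i + u_i,     u_i ~ N(0, tau_arm²),

observed change means are drawn with sampling variance ``sd_i²/n_i``,
within-arm SDs are lognormal, and reporting artefacts mirror the source
literature: a fraction of trials lose their SD and retain a single other
variability statistic (SE, CI, t or P, or nothing), a fraction report only
baseline and final means, and attrition thins the analyzed sample.
Risk-of-bias vectors are constructed to match requested counts of
adequately / inadequately / indeterminately blinded trials.  All
randomness flows from one seed; a fixed (config, seed) pair reproduces the
trial set byte-for-byte through the CSV writer.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .blinding import BlindingStatus
from .trial_data_io import (
    ArmRole,
    ArmSummary,
    Design,
    Drug,
    ROBAssessment,
    ROBLevel,
    TrialRecord,
)


class GenerationError(ValueError):
    pass


class GeneratorConfig(BaseModel):
    """Ground-truth parameters of the generative model.

    Defaults follow the pooled summaries of the motivating literature:
    placebo change ≈ 1.9 points, intervention change ≈ 9.4 points, with
    inadequate blinding shifting them by −0.36 and −1.07 points and
    between-study SDs of 0.8 and 1.6 points respectively.
    """

    model_config = ConfigDict(frozen=True)

    k_adequate: int = Field(default=5, ge=0)
    k_inadequate: int = Field(default=16, ge=0)
    k_indeterminate: int = Field(default=0, ge=0)
    mu_placebo: float = 1.9
    mu_intervention: float = 9.4
    delta_nocebo: float = -0.36
    delta_enhanced: float = -1.07
    tau_placebo: float = Field(default=0.8, ge=0)
    tau_intervention: float = Field(default=1.6, ge=0)
    #: moderator name -> additive effect on the placebo-arm true mean
    moderator_effects: dict[str, float] = Field(default_factory=dict)
    #: moderator name -> additive effect on the intervention-arm true mean
    moderator_effects_intervention: dict[str, float] = Field(default_factory=dict)
    sd_change_lognormal: tuple[float, float] = (1.7, 0.25)
    n_range: tuple[int, int] = (25, 400)
    missing_sd_prob: float = Field(default=0.3, ge=0, le=1)
    #: given a masked SD, which single statistic survives
    retained_stat_probs: dict[str, float] = Field(
        default_factory=lambda: {"se": 0.4, "ci": 0.3, "t": 0.15, "p": 0.15}
    )
    #: given a masked SD, probability that nothing survives (forces matching)
    no_statistic_prob: float = Field(default=0.15, ge=0, le=1)
    final_only_prob: float = Field(default=0.3, ge=0, le=1)
    attrition_beta: tuple[float, float] = (2.0, 18.0)
    geq_base_logit: float = -0.85
    geq_effect: float = 1.95
    #: AE name -> (placebo rate, intervention rate)
    ae_rates: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"headache": (0.04, 0.12), "flushing": (0.015, 0.10)}
    )
    naive_prob: float = Field(default=0.09, ge=0, le=1)
    crossover_prob: float = Field(default=0.1, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.k_adequate + self.k_inadequate + self.k_indeterminate == 0:
            raise ValueError("at least one trial must be generated")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must satisfy 2 <= min <= max")
        total = sum(self.retained_stat_probs.values())
        if self.retained_stat_probs and abs(total - 1.0) > 1e-9:
            raise ValueError("retained_stat_probs must sum to 1")
        if set(self.retained_stat_probs) - {"se", "ci", "t", "p"}:
            raise ValueError("retained_stat_probs keys must be among se/ci/t/p")
        for name, (pp, pi) in self.ae_rates.items():
            if not (0 <= pp <= 1 and 0 <= pi <= 1):
                raise ValueError(f"ae_rates[{name!r}] must be probabilities")
        return self


_DOMAIN_FIELDS = (
    "allocation_concealment",
    "blinding_participant",
    "blinding_caregiver",
    "blinding_assessor",
)


def _rob_vector(status: BlindingStatus, rng: np.random.Generator) -> ROBAssessment:
    if status is BlindingStatus.ADEQUATE:
        levels = [ROBLevel.LOW] * 4
    elif status is BlindingStatus.INADEQUATE:
        if rng.random() < 0.5:
            # at least one high-risk domain
            levels = [
                ROBLevel(rng.choice(["low", "unclear"])) for _ in range(4)
            ]
            levels[int(rng.integers(4))] = ROBLevel.HIGH
        else:
            levels = [ROBLevel.UNCLEAR] * 4
    else:
        # mixed low/unclear: at least one of each, no high
        n_low = int(rng.integers(1, 4))  # 1..3 low domains
        idx = rng.permutation(4)
        levels = [ROBLevel.UNCLEAR] * 4
        for j in idx[:n_low]:
            levels[j] = ROBLevel.LOW
    return ROBAssessment(
        allocation_concealment=levels[0],
        blinding_participant=levels[1],
        blinding_caregiver=levels[2],
        blinding_assessor=levels[3],
        sequence_generation=ROBLevel(rng.choice(["low", "unclear"], p=[0.2, 0.8])),
        itt_analysis=bool(rng.random() < 0.05),
        baseline_balanced=bool(rng.random() < 0.75),
    )


def generate_rob_fixture(
    counts: dict[BlindingStatus | str, int], seed: int = 0
) -> list[ROBAssessment]:
    """Risk-of-bias vectors whose classified statuses match ``counts`` exactly."""
    rng = np.random.default_rng(seed)
    out: list[ROBAssessment] = []
    for status in BlindingStatus:
        n = counts.get(status, counts.get(status.value, 0))
        out.extend(_rob_vector(status, rng) for _ in range(int(n)))
    return out


def _moderators(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    baseline = float(np.clip(rng.normal(13.5, 2.0), 6.0, 25.0))
    return {
        "naive_to_intervention": bool(rng.random() < cfg.naive_prob),
        "pct_prior_experience": float(np.round(rng.beta(2, 3) * 100.0, 1)),
        "baseline_severity": baseline,
        "disease_duration": float(np.round(rng.uniform(1.0, 10.0), 1)),
        "study_duration_weeks": float(rng.choice([4.0, 12.0, 26.0], p=[0.25, 0.6, 0.15])),
        "continent": str(
            rng.choice(
                ["across", "asia", "europe", "north_america", "south_america"],
                p=[0.22, 0.2, 0.16, 0.34, 0.08],
            )
        ),
        "single_center": bool(rng.random() < 0.08),
        "commercial_funding": bool(rng.random() < 0.81),
        "pct_psychogenic": float(np.round(rng.beta(2, 5) * 100.0, 1)),
        "prostate_or_sci": bool(rng.random() < 0.08),
        "n_followups": int(rng.integers(1, 6)),
        "pct_randomized_not_analyzed": 0.0,  # back-filled from attrition below
    }


def _make_arm(
    role: ArmRole,
    theta: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    baseline: float,
    mask_sd: bool,
    retained: Optional[str],
    final_only: bool,
    attrition: float,
) -> ArmSummary:
    n_rand = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
    n_anal = max(2, int(round(n_rand * (1.0 - attrition))))
    n_anal = min(n_anal, n_rand)
    sd = float(rng.lognormal(*cfg.sd_change_lognormal))
    change = float(rng.normal(theta, sd / math.sqrt(n_anal)))
    se = sd / math.sqrt(n_anal)
    geq_p = 1.0 / (1.0 + math.exp(-(cfg.geq_base_logit + (cfg.geq_effect if role is ArmRole.INTERVENTION else 0.0))))
    fields: dict = {
        "arm_role": role,
        "n_randomized": n_rand,
        "n_analyzed": n_anal,
        "baseline_mean": baseline,
        "final_mean": baseline + change,
        "change_mean": None if final_only else change,
        "geq_responders": int(rng.binomial(n_rand, geq_p)),
    }
    for ae, (pp, pi) in cfg.ae_rates.items():
        fields[f"ae_{ae}"] = int(rng.binomial(n_rand, pi if role is ArmRole.INTERVENTION else pp))
    if not mask_sd:
        fields["sd_change"] = sd
    elif retained == "se":
        fields["se"] = se
    elif retained == "ci":
        fields["ci_low"] = change - 1.96 * se
        fields["ci_high"] = change + 1.96 * se
    elif retained == "t":
        fields["t_value"] = change / se
    elif retained == "p":
        t = abs(change) / se
        p = 2.0 * float(stats.t.sf(t, df=n_anal - 1))
        fields["p_value"] = min(max(p, 1e-12), 1.0)
    return ArmSummary(**fields)


def generate_trial_set(config: GeneratorConfig) -> list[TrialRecord]:
    """Draw a full trial set from the generative model (seeded, reproducible)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    statuses = (
        [BlindingStatus.ADEQUATE] * cfg.k_adequate
        + [BlindingStatus.INADEQUATE] * cfg.k_inadequate
        + [BlindingStatus.INDETERMINATE] * cfg.k_indeterminate
    )
    if not statuses:
        raise GenerationError("config generates no trials")
    records: list[TrialRecord] = []
    for i, status in enumerate(statuses):
        tid = f"T{i + 1:03d}"
        rob = _rob_vector(status, rng)
        moderators = _moderators(cfg, rng)
        attrition = float(rng.beta(*cfg.attrition_beta))
        moderators["pct_randomized_not_analyzed"] = float(np.round(attrition * 100.0, 2))

        inadequate = status is BlindingStatus.INADEQUATE
        u_p = float(rng.normal(0.0, cfg.tau_placebo))
        u_i = float(rng.normal(0.0, cfg.tau_intervention))
        theta_p = cfg.mu_placebo + (cfg.delta_nocebo if inadequate else 0.0) + u_p
        theta_i = cfg.mu_intervention + (cfg.delta_enhanced if inadequate else 0.0) + u_i
        for name, beta in cfg.moderator_effects.items():
            theta_p += beta * _numeric_moderator(moderators, name)
        for name, beta in cfg.moderator_effects_intervention.items():
            theta_i += beta * _numeric_moderator(moderators, name)

        mask = rng.random() < cfg.missing_sd_prob
        retained: Optional[str] = None
        if mask:
            if rng.random() < cfg.no_statistic_prob:
                retained = None
            else:
                keys = sorted(cfg.retained_stat_probs)
                probs = [cfg.retained_stat_probs[k] for k in keys]
                retained = str(rng.choice(keys, p=probs))
        final_only = bool(rng.random() < cfg.final_only_prob)
        baseline = moderators["baseline_severity"]

        placebo = _make_arm(
            ArmRole.PLACEBO, theta_p, cfg, rng, baseline, mask, retained, final_only, attrition
        )
        intervention = _make_arm(
            ArmRole.INTERVENTION, theta_i, cfg, rng, baseline, mask, retained, final_only, attrition
        )
        records.append(
            TrialRecord(
                trial_id=tid,
                design=Design.CROSSOVER if rng.random() < cfg.crossover_prob else Design.PARALLEL,
                drug=Drug(rng.choice(["sildenafil", "vardenafil", "tadalafil"], p=[0.5, 0.25, 0.25])),
                publication_year=int(rng.integers(1998, 2013)),
                placebo_arm=placebo,
                intervention_arm=intervention,
                rob=rob,
                moderators=moderators,
            )
        )
    return records


def _numeric_moderator(moderators: dict, name: str) -> float:
    value = moderators.get(name)
    if value is None:
        raise GenerationError(f"moderator effect refers to unknown moderator {name!r}")
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float)):
        return float(value)
    raise GenerationError(f"moderator {name!r} is not numeric; cannot apply a linear effect")


def true_mixture_mean(cfg: GeneratorConfig, arm_role: ArmRole | str) -> float:
    """Analytic mean of the true arm effect over the blinding-status mixture
    (moderator effects aside)."""
    role = ArmRole(arm_role)
    k = cfg.k_adequate + cfg.k_inadequate + cfg.k_indeterminate
    frac_inadequate = cfg.k_inadequate / k
    if role is ArmRole.PLACEBO:
        return cfg.mu_placebo + frac_inadequate * cfg.delta_nocebo
    return cfg.mu_intervention + frac_inadequate * cfg.delta_enhanced
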