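"""Change-score derivation and standard-deviation imputation.

Arms that report no SD for the change score have one reconstructed from the
best available statistic, in a fixed precedence order of ascending
information loss:

1. reported SD (kept as-is);
2. SD = SE * sqrt(n);
3. SE = (ci_high - ci_low) / (2 * 1.96), then rule 2;
4. SE = |change| / |t|, then rule 2;
5. t from the inverse central t distribution at the two-sided P with
   df = n - 1, then rule 4.

Arms for which no rule applies go to matched-study substitution: a seeded
random subset of them — capped so that substituted arms stay at or below a
fraction (default 33%) of the analysis set — receives the SD of the
same-role arm whose analyzed sample size is closest (ties broken by the
lexicographically smallest donor trial id).  Arms not selected are flagged
excluded and drop out of downstream pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .trial_data_io import ArmRole, ArmSummary, TrialRecord

#: Normal multiplier used to convert a 95% CI to a standard error.
Z95 = 1.96

ImputationMethod = Literal[
    "reported", "from_se", "from_ci", "from_t", "from_p", "matched_donor", "failed"
]


class DerivationError(ValueError):
    """A change score can be neither read nor derived for an arm."""


class SubstitutionError(ValueError):
    """Matched-study substitution has no donor arms to draw from."""


@dataclass
class ImputationReport:
    """Provenance of one arm's SD after the cascade."""

    trial_id: str
    arm_role: str
    method: ImputationMethod
    donor_id: Optional[str] = None
    resulting_sd: Optional[float] = None
    excluded: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if (self.method == "matched_donor") != (self.donor_id is not None):
            raise ValueError("donor_id must be present iff method is 'matched_donor'")
        if self.method != "failed" and not (self.resulting_sd and self.resulting_sd > 0):
            raise ValueError("resulting_sd must be positive unless the method is 'failed'")


def derive_change_score(arm: ArmSummary) -> ArmSummary:
    """Fill ``change_mean`` as final − baseline; a reported change wins."""
    if arm.change_mean is not None:
        return arm
    if arm.baseline_mean is not None and arm.final_mean is not None:
        return arm.model_copy(update={"change_mean": arm.final_mean - arm.baseline_mean})
    raise DerivationError(
        "change score unavailable: need change_mean, or both baseline_mean and final_mean"
    )


def impute_sd(
    arm: ArmSummary, df_rule: Literal["n_minus_1"] = "n_minus_1"
) -> tuple[Optional[float], ImputationMethod]:
    """Return ``(sd, method)`` from the first applicable cascade rule.

    ``method`` is ``"failed"`` (with ``sd=None``) when no statistic applies;
    the caller hands such arms to :func:`matched_sd_substitution`.
    """
    if df_rule != "n_minus_1":
        raise ValueError(f"unsupported df rule {df_rule!r}")
    n = arm.n_analyzed
    sqrt_n = math.sqrt(n)
    if arm.sd_change is not None:
        return arm.sd_change, "reported"
    if arm.se is not None:
        return arm.se * sqrt_n, "from_se"
    if arm.ci_low is not None and arm.ci_high is not None and arm.ci_high > arm.ci_low:
        se = (arm.ci_high - arm.ci_low) / (2.0 * Z95)
        return se * sqrt_n, "from_ci"
    if arm.t_value is not None and arm.change_mean is not None:
        t = abs(arm.t_value)
        if t > 0 and arm.change_mean != 0:
            se = abs(arm.change_mean) / t
            return se * sqrt_n, "from_t"
    if arm.p_value is not None and arm.change_mean is not None and n >= 2:
        t = float(stats.t.ppf(1.0 - arm.p_value / 2.0, df=n - 1))
        if t > 0 and arm.change_mean != 0:
            se = abs(arm.change_mean) / t
            return se * sqrt_n, "from_p"
    return None, "failed"


def _max_substitutions(n_with_sd: int, n_failed: int, max_fraction: float) -> int:
    """Largest m ≤ n_failed with m / (n_with_sd + m) ≤ max_fraction."""
    m = 0
    while m < n_failed and (m + 1) / (n_with_sd + m + 1) <= max_fraction:
        m += 1
    return m


def matched_sd_substitution(
    records: list[TrialRecord],
    max_fraction: float = 0.33,
    seed: int = 0,
) -> tuple[list[TrialRecord], list[ImputationReport]]:
    """Substitute missing SDs from sample-size-matched same-role arms.

    Operates per arm role.  A seeded uniform random subset of the failed
    arms is selected, capped so substituted arms never exceed
    ``max_fraction`` of that role's analysis set; each selected arm gets the
    SD of the donor arm minimizing ``|n_donor − n_recipient|`` (analyzed n),
    ties going to the lexicographically smallest donor trial id.  Unselected
    failed arms are reported as excluded.
    """
    rng = np.random.default_rng(seed)
    out = {rec.trial_id: rec for rec in records}
    reports: list[ImputationReport] = []

    for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
        donors: list[tuple[str, ArmSummary]] = []
        failed: list[str] = []
        for rec in records:
            arm = rec.arm(role)
            sd, method = impute_sd(arm)
            if method == "failed":
                failed.append(rec.trial_id)
            else:
                donors.append((rec.trial_id, arm.model_copy(update={"sd_change": sd})))
        if not failed:
            continue
        if not donors:
            raise SubstitutionError(f"no donor arms with SD available for role {role.value!r}")
        m = _max_substitutions(len(donors), len(failed), max_fraction)
        failed_sorted = sorted(failed)
        chosen = set(rng.choice(failed_sorted, size=m, replace=False)) if m else set()
        for tid in failed_sorted:
            rec = out[tid]
            recipient = rec.arm(role)
            if tid not in chosen:
                reports.append(
                    ImputationReport(
                        trial_id=tid,
                        arm_role=role.value,
                        method="failed",
                        excluded=True,
                        note="missing SD, not drawn for matched substitution",
                    )
                )
                continue
            donor_id, donor_arm = min(
                donors, key=lambda d: (abs(d[1].n_analyzed - recipient.n_analyzed), d[0])
            )
            out[tid] = rec.with_arm(
                recipient.model_copy(update={"sd_change": donor_arm.sd_change})
            )
            reports.append(
                ImputationReport(
                    trial_id=tid,
                    arm_role=role.value,
                    method="matched_donor",
                    donor_id=donor_id,
                    resulting_sd=donor_arm.sd_change,
                )
            )

    return [out[rec.trial_id] for rec in records], reports


def impute_trial_set(
    records: list[TrialRecord],
    seed: int = 0,
    max_matched_fraction: float = 0.33,
) -> tuple[list[TrialRecord], list[ImputationReport]]:
    """Run the full cascade over a trial set.

    Derives change scores, resolves SDs via the precedence rules, then
    applies matched substitution to the remainder.  Returns the updated
    records and one report per arm.  Idempotent: a second pass leaves the
    records unchanged (resolved SDs re-enter as ``reported``).
    """
    staged: list[TrialRecord] = []
    reports: list[ImputationReport] = []
    derivable: list[bool] = []
    for rec in records:
        ok = True
        for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
            arm = rec.arm(role)
            try:
                rec = rec.with_arm(derive_change_score(arm))
            except DerivationError:
                ok = False
                reports.append(
                    ImputationReport(
                        trial_id=rec.trial_id,
                        arm_role=role.value,
                        method="failed",
                        excluded=True,
                        note="change score underivable",
                    )
                )
        staged.append(rec)
        derivable.append(ok)

    resolved: list[TrialRecord] = []
    for rec, ok in zip(staged, derivable):
        if not ok:
            resolved.append(rec)
            continue
        for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
            arm = rec.arm(role)
            sd, method = impute_sd(arm)
            if method != "failed":
                note = "conservative: P reported as an inequality" if (
                    method == "from_p" and arm.p_is_bound
                ) else ""
                reports.append(
                    ImputationReport(
                        trial_id=rec.trial_id,
                        arm_role=role.value,
                        method=method,
                        resulting_sd=sd,
                        note=note,
                    )
                )
                if arm.sd_change is None:
                    rec = rec.with_arm(arm.model_copy(update={"sd_change": sd}))
        resolved.append(rec)

    candidates = [rec for rec, ok in zip(resolved, derivable) if ok]
    substituted, sub_reports = matched_sd_substitution(
        candidates, max_fraction=max_matched_fraction, seed=seed
    )
    by_id = {rec.trial_id: rec for rec in substituted}
    final = [by_id.get(rec.trial_id, rec) for rec in resolved]
    reports.extend(sub_reports)
    return final, reports
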