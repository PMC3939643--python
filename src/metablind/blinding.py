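"""Blinding classification and nocebo / enhanced-placebo stratum comparisons.

A trial is *adequately* blinded when all four blinding-related
risk-of-bias domains (allocation concealment; blinding of participant,
caregiver and outcome assessor) are rated low; *inadequately* blinded when
any domain is high or all four are unclear; otherwise *indeterminate*
(mixed low/unclear) and excluded from the primary adequate-vs-inadequate
comparison.

The nocebo effect is the difference in pooled placebo-arm change scores
between adequately and inadequately blinded trials; the enhanced-placebo
effect is the analogous difference for intervention arms.  Differences are
``d = mu_adequate − mu_inadequate`` with ``se_d = sqrt(se_a² + se_b²)``, a
normal (optionally Student-t) test of no difference, and a between-stratum
heterogeneity Q on one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from scipy import stats

from .pooling import Z95, PooledEstimate, arm_effect_inputs, pool_random
from .trial_data_io import BLINDING_DOMAINS, ArmRole, ROBAssessment, ROBLevel, TrialRecord


class BlindingStatus(str, Enum):
    ADEQUATE = "adequate"
    INADEQUATE = "inadequate"
    INDETERMINATE = "indeterminate"


class ComparisonError(ValueError):
    """A stratum comparison cannot be computed (e.g. an empty stratum)."""


def classify_blinding(rob: ROBAssessment) -> BlindingStatus:
    """Classify a trial's blinding status from its four blinding domains.

    Total over all 3^4 = 81 level combinations: adequate iff all four low;
    inadequate iff any high or all four unclear; indeterminate otherwise.
    """
    levels = [getattr(rob, d) for d in BLINDING_DOMAINS]
    if all(lv is ROBLevel.LOW for lv in levels):
        return BlindingStatus.ADEQUATE
    if any(lv is ROBLevel.HIGH for lv in levels) or all(lv is ROBLevel.UNCLEAR for lv in levels):
        return BlindingStatus.INADEQUATE
    return BlindingStatus.INDETERMINATE


@dataclass(frozen=True)
class StratumComparison:
    """Difference between two pooled strata (e.g. adequate vs inadequate).

    ``relative_percent`` is ``100·d / mu_a`` (``None`` when the reference
    stratum mean is within ``1e-8`` of zero).  ``q_between`` is the
    between-stratum heterogeneity Q over the two pooled estimates (1 df);
    ``q_total`` is the heterogeneity Q of the combined study set, reported
    alongside because published tables sometimes print that instead.
    """

    label: str
    pooled_a: Optional[PooledEstimate]
    pooled_b: Optional[PooledEstimate]
    d: float = float("nan")
    se_d: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    z: float = float("nan")
    p: float = float("nan")
    relative_percent: Optional[float] = None
    q_between: float = float("nan")
    p_between: float = float("nan")
    i2_between: float = float("nan")
    q_total: Optional[float] = None
    estimable: bool = True
    note: str = ""


def compare_pooled(
    pooled_a: PooledEstimate,
    pooled_b: PooledEstimate,
    label: str = "summary",
    use_t: bool = False,
    q_total: Optional[float] = None,
) -> StratumComparison:
    """Difference statistics between two already-pooled estimates.

    ``use_t`` switches the test of no difference from the normal
    approximation to Student t with ``k_a + k_b − 2`` degrees of freedom.
    """
    d = pooled_a.mu - pooled_b.mu
    se_d = (pooled_a.se ** 2 + pooled_b.se ** 2) ** 0.5
    z = d / se_d
    if use_t:
        df = max(pooled_a.k + pooled_b.k - 2, 1)
        p = 2.0 * float(stats.t.sf(abs(z), df))
    else:
        p = 2.0 * float(stats.norm.sf(abs(z)))
    w_a, w_b = 1.0 / pooled_a.se ** 2, 1.0 / pooled_b.se ** 2
    m_bar = (w_a * pooled_a.mu + w_b * pooled_b.mu) / (w_a + w_b)
    q_between = w_a * (pooled_a.mu - m_bar) ** 2 + w_b * (pooled_b.mu - m_bar) ** 2
    p_between = float(stats.chi2.sf(q_between, 1))
    i2_between = max(0.0, 100.0 * (q_between - 1.0) / q_between) if q_between > 0 else 0.0
    rel = 100.0 * d / pooled_a.mu if abs(pooled_a.mu) >= 1e-8 else None
    return StratumComparison(
        label=label,
        pooled_a=pooled_a,
        pooled_b=pooled_b,
        d=d,
        se_d=se_d,
        ci_low=d - Z95 * se_d,
        ci_high=d + Z95 * se_d,
        z=z,
        p=p,
        relative_percent=rel,
        q_between=q_between,
        p_between=p_between,
        i2_between=i2_between,
        q_total=q_total,
    )


def compare_strata(
    records_a: Sequence[TrialRecord],
    records_b: Sequence[TrialRecord],
    arm_role: ArmRole | str,
    label: str = "summary",
    use_t: bool = False,
) -> StratumComparison:
    """Pool each stratum (random effects) and compare the pooled means."""
    if not records_a or not records_b:
        raise ComparisonError(f"{label}: both strata must be non-empty")
    role = ArmRole(arm_role)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k = 1 strata degrade to fixed-effect
        pooled_a = pool_random(arm_effect_inputs(records_a, role))
        pooled_b = pool_random(arm_effect_inputs(records_b, role))
    combined = pool_random(arm_effect_inputs(list(records_a) + list(records_b), role))
    return compare_pooled(pooled_a, pooled_b, label=label, use_t=use_t, q_total=combined.Q)


def classify_records(
    records: Sequence[TrialRecord],
) -> dict[BlindingStatus, list[TrialRecord]]:
    """Partition records by blinding status."""
    out: dict[BlindingStatus, list[TrialRecord]] = {s: [] for s in BlindingStatus}
    for rec in records:
        out[classify_blinding(rec.rob)].append(rec)
    return out


def rob_domain_comparisons(
    records: Sequence[TrialRecord],
    arm_role: ArmRole | str,
    use_t: bool = False,
) -> list[StratumComparison]:
    """One low-vs-(unclear∪high) comparison per blinding domain, plus the
    adequate-vs-inadequate summary row (indeterminate trials excluded).

    Rows whose strata cannot both be populated are returned flagged
    non-estimable; the remaining rows are still computed.
    """
    rows: list[StratumComparison] = []
    for domain in BLINDING_DOMAINS:
        low = [r for r in records if getattr(r.rob, domain) is ROBLevel.LOW]
        other = [r for r in records if getattr(r.rob, domain) is not ROBLevel.LOW]
        rows.append(_safe_compare(low, other, arm_role, domain, use_t))
    strata = classify_records(records)
    rows.append(
        _safe_compare(
            strata[BlindingStatus.ADEQUATE],
            strata[BlindingStatus.INADEQUATE],
            arm_role,
            "summary",
            use_t,
        )
    )
    return rows


def _safe_compare(
    records_a: Sequence[TrialRecord],
    records_b: Sequence[TrialRecord],
    arm_role: ArmRole | str,
    label: str,
    use_t: bool,
) -> StratumComparison:
    if not records_a or not records_b:
        empty = "low-risk" if not records_a else "unclear/high-risk"
        if label == "summary":
            empty = "adequately blinded" if not records_a else "inadequately blinded"
        return StratumComparison(
            label=label,
            pooled_a=None,
            pooled_b=None,
            estimable=False,
            note=f"not estimable: empty {empty} stratum",
        )
    return compare_strata(records_a, records_b, arm_role, label=label, use_t=use_t)
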