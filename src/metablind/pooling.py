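"""Generic inverse-variance pooling of within-arm change scores.

Fixed-effect and DerSimonian–Laird random-effects pooling of study-level
effects (mean IIEF-EF change per arm, ``v_i = sd_i^2 / n_i``), the usual
heterogeneity statistics (Q, I², tau²), and risk ratios with a Haldane
half-integer continuity correction for dichotomous outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .trial_data_io import ArmRole, TrialRecord

#: Normal multiplier for 95% confidence intervals (RevMan convention).
Z95 = 1.96


class PoolingError(ValueError):
    """Inputs do not satisfy the pooling preconditions."""


@dataclass(frozen=True)
class EffectInput:
    """One study's effect estimate ``y`` and within-study variance ``v``."""

    trial_id: str
    y: float
    v: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise PoolingError(f"{self.trial_id}: effect estimate must be finite")
        if not (math.isfinite(self.v) and self.v > 0):
            raise PoolingError(f"{self.trial_id}: variance must be positive, got {self.v}")


@dataclass(frozen=True)
class PooledEstimate:
    """A pooled mean with its SE, 95% CI and heterogeneity statistics.

    ``Q``/``p_Q``/``i2``/``tau2`` are ``None`` when the estimate was built
    from a printed summary (:func:`pooled_from_summary`) rather than from
    study-level inputs.
    """

    mu: float
    se: float
    ci_low: float
    ci_high: float
    k: int
    n_total: int
    Q: Optional[float]
    df: int
    p_Q: Optional[float]
    i2: Optional[float]
    tau2: Optional[float]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise PoolingError("pooled SE must be positive")
        if self.weights and abs(sum(self.weights) - 1.0) > 1e-12:
            raise PoolingError("normalized weights must sum to 1")


def _finish(
    inputs: Sequence[EffectInput],
    w_star: np.ndarray,
    Q: float,
    tau2: float,
) -> PooledEstimate:
    y = np.array([e.y for e in inputs], dtype=float)
    k = len(inputs)
    df = k - 1
    sw = float(w_star.sum())
    mu = float((w_star * y).sum() / sw)
    se = sw ** -0.5
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    return PooledEstimate(
        mu=mu,
        se=se,
        ci_low=mu - Z95 * se,
        ci_high=mu + Z95 * se,
        k=k,
        n_total=sum(e.n or 0 for e in inputs),
        Q=Q,
        df=df,
        p_Q=p_Q,
        i2=i2,
        tau2=tau2,
        weights=tuple(w_star / sw),
    )


def pool_fixed(inputs: Sequence[EffectInput]) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling (``w_i = 1/v_i``)."""
    if not inputs:
        raise PoolingError("cannot pool an empty set of studies")
    w = np.array([1.0 / e.v for e in inputs], dtype=float)
    y = np.array([e.y for e in inputs], dtype=float)
    mu = float((w * y).sum() / w.sum())
    Q = float((w * (y - mu) ** 2).sum())
    return _finish(inputs, w, Q, tau2=0.0)


def pool_random(
    inputs: Sequence[EffectInput],
    tau2_method: Literal["dersimonian_laird"] = "dersimonian_laird",
) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooling.

    ``tau² = max(0, (Q − df) / (Σw − Σw²/Σw))`` from fixed-effect weights,
    then re-weighting by ``1/(v_i + tau²)``.  A single study degrades to the
    fixed-effect estimate with a warning.
    """
    if tau2_method != "dersimonian_laird":
        raise PoolingError(f"unsupported tau2 method {tau2_method!r}")
    if not inputs:
        raise PoolingError("cannot pool an empty set of studies")
    if len(inputs) == 1:
        warnings.warn("single study: random-effects pooling degrades to fixed-effect")
        return pool_fixed(inputs)
    w = np.array([1.0 / e.v for e in inputs], dtype=float)
    y = np.array([e.y for e in inputs], dtype=float)
    v = np.array([e.v for e in inputs], dtype=float)
    mu_fe = float((w * y).sum() / w.sum())
    Q = float((w * (y - mu_fe) ** 2).sum())
    df = len(inputs) - 1
    denom = float(w.sum() - (w ** 2).sum() / w.sum())
    tau2 = max(0.0, (Q - df) / denom)
    w_star = 1.0 / (v + tau2)
    return _finish(inputs, w_star, Q, tau2=tau2)


def pooled_from_summary(
    mu: float, ci_low: float, ci_high: float, k: int = 0, n_total: int = 0
) -> PooledEstimate:
    """Build a :class:`PooledEstimate` from a printed mean and 95% CI.

    Used to compare against published stratum summaries: the SE is
    back-calculated as ``(ci_high − ci_low) / (2 · 1.96)``; heterogeneity
    fields are unknown and set to ``None``.
    """
    if ci_high <= ci_low:
        raise PoolingError("ci_high must exceed ci_low")
    se = (ci_high - ci_low) / (2.0 * Z95)
    return PooledEstimate(
        mu=mu,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        k=k,
        n_total=n_total,
        Q=None,
        df=max(k - 1, 0),
        p_Q=None,
        i2=None,
        tau2=None,
        weights=(),
    )


def arm_effect_inputs(
    records: Sequence[TrialRecord], arm_role: ArmRole | str
) -> list[EffectInput]:
    """Study-level effect inputs for one arm role: ``y = change``, ``v = sd²/n``."""
    role = ArmRole(arm_role)
    out: list[EffectInput] = []
    for rec in records:
        arm = rec.arm(role)
        if arm.change_mean is None or arm.sd_change is None:
            raise PoolingError(
                f"trial {rec.trial_id!r}, {role.value} arm: change score or SD missing — "
                "run the imputation stage first"
            )
        out.append(
            EffectInput(
                trial_id=rec.trial_id,
                y=arm.change_mean,
                v=arm.sd_change ** 2 / arm.n_analyzed,
                n=arm.n_analyzed,
            )
        )
    return out


@dataclass(frozen=True)
class RiskRatioResult:
    """A 2×2 risk ratio with 95% CI on the log scale."""

    rr: float
    ci_low: float
    ci_high: float
    log_rr: float
    se_log_rr: float
    a: int
    n1: int
    c: int
    n2: int
    corrected: bool
    estimable: bool = True


def risk_ratio(
    a: int,
    n1: int,
    c: int,
    n2: int,
    zero_cell: Literal["haldane_half"] = "haldane_half",
) -> RiskRatioResult:
    """Risk ratio ``(a/n1) / (c/n2)`` with a 95% CI.

    With ``a = 0`` or ``c = 0`` (but not both) 0.5 is added to all four
    cells of the 2×2 table (Haldane correction) and ``corrected`` is set;
    ``a = c = 0`` yields a flagged non-estimable null result.
    """
    if zero_cell != "haldane_half":
        raise ValueError(f"unsupported zero-cell strategy {zero_cell!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise ValueError("event counts must lie within their denominators")
    if a == 0 and c == 0:
        return RiskRatioResult(
            rr=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            log_rr=float("nan"),
            se_log_rr=float("nan"),
            a=a,
            n1=n1,
            c=c,
            n2=n2,
            corrected=False,
            estimable=False,
        )
    corrected = a == 0 or c == 0
    if corrected:
        fa, fb = a + 0.5, (n1 - a) + 0.5
        fc, fd = c + 0.5, (n2 - c) + 0.5
    else:
        fa, fb, fc, fd = float(a), float(n1 - a), float(c), float(n2 - c)
    fn1, fn2 = fa + fb, fc + fd
    log_rr = math.log((fa / fn1) / (fc / fn2))
    se = math.sqrt(1.0 / fa - 1.0 / fn1 + 1.0 / fc - 1.0 / fn2)
    return RiskRatioResult(
        rr=math.exp(log_rr),
        ci_low=math.exp(log_rr - Z95 * se),
        ci_high=math.exp(log_rr + Z95 * se),
        log_rr=log_rr,
        se_log_rr=se,
        a=a,
        n1=n1,
        c=c,
        n2=n2,
        corrected=corrected,
    )
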