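"""Inverse-variance weighted meta-regression with a REML variance component.

Study-level effects ``y_i`` with known sampling variances ``v_i`` are
modeled as ``y_i = x_i' beta + u_i + e_i`` with ``u_i ~ N(0, tau²)`` and
``e_i ~ N(0, v_i)``.  ``tau²`` maximizes the restricted log-likelihood

    -0.5 * [ sum log(v_i + tau²) + log|X' W X| + sum w_i r_i² ],

with ``w_i = 1/(v_i + tau²)`` and GLS residuals ``r``, via Fisher scoring
projected at zero.  Coefficients are GLS at the converged ``tau²``;
standardized coefficients rescale each non-intercept column and the
outcome to unit weighted variance.  The fraction of between-study variance
explained is ``max(0, 100·(1 − tau²_res / tau²_null))`` against the
intercept-only fit on the same studies.

Moderators come either from the record's own fields (``sample_size``,
``publication_year``, ``parallel_design``, ``drug``, ``placebo_effect``)
or from its moderator map; categoricals expand to dummies against a stated
reference level (continent: north_america; drug: tadalafil).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pooling import arm_effect_inputs
from .trial_data_io import ArmRole, Design, TrialRecord


class RegressionError(ValueError):
    pass


class CollinearityError(RegressionError):
    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is collinear in column(s): {columns}")


@dataclass
class RegressionTerm:
    name: str
    beta: float
    se: float
    p: float
    beta_std: float  # NaN for the intercept
    se_std: float


@dataclass
class RegressionResult:
    outcome_arm: str
    terms: list[RegressionTerm]
    tau2_res: float
    tau2_null: float
    r2_explained: float
    k: int
    converged: bool
    iterations: int
    moderator: str = ""
    entry_order: list[str] = field(default_factory=list)
    estimable: bool = True
    note: str = ""


def _reml_tau2(
    y: np.ndarray, v: np.ndarray, X: np.ndarray, tol: float, max_iter: int
) -> tuple[float, bool, int]:
    """Fisher-scoring REML estimate of tau², projected at zero."""
    k, p = X.shape
    tau2 = max(0.0, float(np.var(y, ddof=1) - v.mean())) if k > 1 else 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / (v + tau2)
        WX = X * w[:, None]
        XtWX = X.T @ WX
        XtWX_inv = np.linalg.inv(XtWX)
        beta = XtWX_inv @ (WX.T @ y)
        r = y - X @ beta
        Py = w * r
        # P = W - WX (X'WX)^{-1} X'W ; score and expected information in tau²
        H = WX @ XtWX_inv @ WX.T
        P = np.diag(w) - H
        score = -0.5 * (np.trace(P) - float(Py @ Py))
        info = 0.5 * float((P * P).sum())
        if tau2 == 0.0 and score <= 0.0:
            converged = True
            break
        step = score / info
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    return tau2, converged, it


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood profile in tau² (additive constant dropped)."""
    w = 1.0 / (v + tau2)
    WX = X * w[:, None]
    XtWX = X.T @ WX
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtWX, WX.T @ y)
    r = y - X @ beta
    return -0.5 * (float(np.log(v + tau2).sum()) + logdet + float((w * r * r).sum()))


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = [names[j] for j in range(X.shape[1]) if diag[j] < 1e-10 * max(diag.max(), 1.0)]
    if bad:
        raise CollinearityError(bad)


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    m = float((w * x).sum() / w.sum())
    return math.sqrt(float((w * (x - m) ** 2).sum() / w.sum()))


def reml_meta_regress(
    y: Sequence[float],
    v: Sequence[float],
    X: np.ndarray,
    names: Sequence[str],
    outcome_arm: str = "",
    tol: float = 1e-8,
    max_iter: int = 200,
    standardize: str = "weighted",
) -> RegressionResult:
    """Fit the weighted random-effects regression; ``X`` includes an intercept.

    ``standardize`` is ``"weighted"`` (moments under weights
    ``1/(v_i + tau²)``) or ``"unweighted"``.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.asarray(X, dtype=float)
    k, p = X.shape
    if k <= p:
        raise RegressionError(f"need more studies ({k}) than coefficients ({p})")
    if np.any(v <= 0):
        raise RegressionError("all sampling variances must be positive")
    _check_collinearity(X, names)

    tau2, converged, iters = _reml_tau2(y, v, X, tol, max_iter)
    w = 1.0 / (v + tau2)
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    beta = XtWX_inv @ (WX.T @ y)
    se = np.sqrt(np.diag(XtWX_inv))
    pvals = 2.0 * stats.norm.sf(np.abs(beta) / se)

    sw = w if standardize == "weighted" else np.ones_like(w)
    sd_y = _weighted_sd(y, sw)
    terms: list[RegressionTerm] = []
    for j, name in enumerate(names):
        is_intercept = name == "intercept"
        if is_intercept or sd_y == 0:
            b_std = float("nan")
            s_std = float("nan")
        else:
            sd_x = _weighted_sd(X[:, j], sw)
            scale = sd_x / sd_y if sd_y > 0 else float("nan")
            b_std = float(beta[j] * scale)
            s_std = float(se[j] * scale)
        terms.append(
            RegressionTerm(
                name=name,
                beta=float(beta[j]),
                se=float(se[j]),
                p=float(min(pvals[j], 1.0)),
                beta_std=b_std,
                se_std=s_std,
            )
        )

    if p == 1:
        tau2_null = tau2
    else:
        tau2_null, _, _ = _reml_tau2(y, v, np.ones((k, 1)), tol, max_iter)
    if tau2_null > 0:
        r2 = max(0.0, min(100.0, 100.0 * (1.0 - tau2 / tau2_null)))
    else:
        r2 = 0.0
    return RegressionResult(
        outcome_arm=outcome_arm,
        terms=terms,
        tau2_res=tau2,
        tau2_null=tau2_null,
        r2_explained=r2,
        k=k,
        converged=converged,
        iterations=iters,
    )


# --------------------------------------------------------------------------
# moderator extraction
# --------------------------------------------------------------------------

CONTINENT_REFERENCE = "north_america"
DRUG_REFERENCE = "tadalafil"

#: Moderators computed from record fields rather than the moderator map.
DERIVED_MODERATORS = ("sample_size", "publication_year", "parallel_design", "drug", "placebo_effect")


def moderator_columns(
    records: Sequence[TrialRecord], name: str, arm_role: ArmRole | str
) -> tuple[list[Optional[float]] | None, list[str]]:
    """Raw column values (one list per expanded dummy) for a moderator.

    Returns ``(values, names)`` where ``values[i]`` is the row for record
    ``i`` (``None`` marks unobserved) and ``names`` the expanded column
    names.  Categorical moderators yield one dummy per non-reference level
    observed in the data.
    """
    role = ArmRole(arm_role)

    def raw(rec: TrialRecord) -> Optional[object]:
        if name == "sample_size":
            return rec.placebo_arm.n_randomized + rec.intervention_arm.n_randomized
        if name == "publication_year":
            return rec.publication_year
        if name == "parallel_design":
            return rec.design is Design.PARALLEL
        if name == "drug":
            return rec.drug.value
        if name == "placebo_effect":
            if role is not ArmRole.INTERVENTION:
                raise RegressionError("placebo_effect is a covariate for intervention outcomes only")
            return rec.placebo_arm.change_mean
        return rec.moderators.get(name)

    values = [raw(rec) for rec in records]
    if name in ("continent", "drug"):
        ref = CONTINENT_REFERENCE if name == "continent" else DRUG_REFERENCE
        levels = sorted({v for v in values if v is not None and v != ref})
        cols = []
        for level in levels:
            cols.append([None if v is None else float(v == level) for v in values])
        return cols, [f"{name}[{level}]" for level in levels]
    numeric = [
        None if v is None else float(v) if not isinstance(v, bool) else float(v) for v in values
    ]
    return [numeric], [name]


def _design_for(
    records: Sequence[TrialRecord],
    moderator_names: Sequence[str],
    arm_role: ArmRole | str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[TrialRecord]]:
    """Complete-case y, v, X over the requested moderators."""
    cols: list[list[Optional[float]]] = []
    names: list[str] = ["intercept"]
    for m in moderator_names:
        values, sub_names = moderator_columns(records, m, arm_role)
        cols.extend(values)
        names.extend(sub_names)
    keep = [
        i
        for i in range(len(records))
        if all(col[i] is not None for col in cols)
    ]
    subset = [records[i] for i in keep]
    effects = arm_effect_inputs(subset, arm_role)
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    X = np.column_stack(
        [np.ones(len(keep))] + [np.array([col[i] for i in keep], dtype=float) for col in cols]
    ) if keep else np.ones((0, 1 + len(cols)))
    return y, v, X, names, subset


def univariate_screen(
    records: Sequence[TrialRecord],
    arm_role: ArmRole | str,
    moderators: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[RegressionResult]:
    """One single-moderator REML regression per name, on the records where
    that moderator is observed.  Constant or unestimable moderators yield a
    flagged non-estimable row."""
    role = ArmRole(arm_role)
    out: list[RegressionResult] = []
    for name in moderators:
        try:
            y, v, X, names, subset = _design_for(records, [name], role)
            if len(y) == 0:
                raise RegressionError("moderator observed on no records")
            for j in range(1, X.shape[1]):
                if np.ptp(X[:, j]) == 0:
                    raise RegressionError(f"moderator {names[j]!r} is constant on its subset")
            res = reml_meta_regress(
                y, v, X, names, outcome_arm=role.value, tol=tol, max_iter=max_iter
            )
            res.moderator = name
            out.append(res)
        except RegressionError as exc:
            out.append(
                RegressionResult(
                    outcome_arm=role.value,
                    terms=[],
                    tau2_res=float("nan"),
                    tau2_null=float("nan"),
                    r2_explained=float("nan"),
                    k=0,
                    converged=False,
                    iterations=0,
                    moderator=name,
                    estimable=False,
                    note=f"not estimable: {exc}",
                )
            )
    return out


def forward_stepwise(
    records: Sequence[TrialRecord],
    arm_role: ArmRole | str,
    candidates: Sequence[str],
    p_enter: float = 0.15,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RegressionResult:
    """Forward-stepwise REML regression with a lax entry criterion.

    Starting from the intercept-only model, each step refits with every
    remaining candidate added and admits the one with the smallest
    coefficient p value, provided it is below ``p_enter`` (a categorical
    block enters on its smallest dummy p).  Stops when no candidate
    qualifies; the entry order is recorded.
    """
    role = ArmRole(arm_role)
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        best: tuple[float, str] | None = None
        for cand in remaining:
            try:
                y, v, X, names, _ = _design_for(records, selected + [cand], role)
                res = reml_meta_regress(
                    y, v, X, names, outcome_arm=role.value, tol=tol, max_iter=max_iter
                )
            except RegressionError:
                continue
            cand_ps = [t.p for t in res.terms if t.name == cand or t.name.startswith(f"{cand}[")]
            if not cand_ps:
                continue
            p_min = min(cand_ps)
            if best is None or p_min < best[0]:
                best = (p_min, cand)
        if best is None or best[0] >= p_enter:
            break
        selected.append(best[1])
        remaining.remove(best[1])

    y, v, X, names, subset = _design_for(records, selected, role)
    res = reml_meta_regress(y, v, X, names, outcome_arm=role.value, tol=tol, max_iter=max_iter)
    res.entry_order = selected
    res.moderator = "+".join(selected) if selected else "(intercept only)"
    return res
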