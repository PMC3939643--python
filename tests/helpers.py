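"""Shared builders and independent oracles for the test suite.

Oracles are written from the closed-form definitions (plain arithmetic /
grid search), independent of the package's code paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from metablind import ArmSummary, ROBAssessment, TrialRecord


def make_arm(role: str = "placebo", n: int = 100, change: float | None = 2.0,
             sd: float | None = 5.0, **kw) -> ArmSummary:
    return ArmSummary(
        arm_role=role,
        n_randomized=kw.pop("n_randomized", n),
        n_analyzed=n,
        change_mean=change,
        sd_change=sd,
        **kw,
    )


def make_rob(levels=("low", "low", "low", "low"), **kw) -> ROBAssessment:
    return ROBAssessment(
        allocation_concealment=levels[0],
        blinding_participant=levels[1],
        blinding_caregiver=levels[2],
        blinding_assessor=levels[3],
        **kw,
    )


def make_record(tid: str, rob_levels=("low",) * 4, placebo: ArmSummary | None = None,
                intervention: ArmSummary | None = None, **kw) -> TrialRecord:
    return TrialRecord(
        trial_id=tid,
        design=kw.pop("design", "parallel"),
        drug=kw.pop("drug", "sildenafil"),
        publication_year=kw.pop("publication_year", 2005),
        placebo_arm=placebo or make_arm("placebo"),
        intervention_arm=intervention or make_arm("intervention", change=9.0),
        rob=make_rob(rob_levels),
        **kw,
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def dl_pool_oracle(y, v):
    """Closed-form DerSimonian-Laird pooling, written out longhand."""
    k = len(y)
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    mu_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    Q = sum(wi * (yi - mu_fe) ** 2 for wi, yi in zip(w, y))
    denom = sw - sum(wi ** 2 for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    ws = [1.0 / (vi + tau2) for vi in v]
    sws = sum(ws)
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sws
    se = sws ** -0.5
    return mu, se, Q, tau2


def risk_ratio_oracle(a, n1, c, n2):
    """Risk ratio and log-scale SE from the 2x2 proportions, longhand."""
    rr = (a / n1) / (c / n2)
    se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2)
    lo = math.exp(math.log(rr) - 1.96 * se)
    hi = math.exp(math.log(rr) + 1.96 * se)
    return rr, se, lo, hi


def reml_grid_oracle(y, v, X, upper=10.0, step=1e-4):
    """Vectorized grid search of the restricted likelihood over tau2."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    grid = np.arange(0.0, upper + step / 2, step)
    w = 1.0 / (v[None, :] + grid[:, None])  # (G, k)
    # X' W X for every grid point: (G, p, p)
    XtWX = np.einsum("gk,kp,kq->gpq", w, X, X)
    sign, logdet = np.linalg.slogdet(XtWX)
    rhs = np.einsum("gk,kp->gp", w * y[None, :], X)
    beta = np.linalg.solve(XtWX, rhs[..., None])[..., 0]  # (G, p)
    r = y[None, :] - beta @ X.T
    ll = -0.5 * (np.log(v[None, :] + grid[:, None]).sum(axis=1) + logdet
                 + (w * r * r).sum(axis=1))
    return float(grid[np.argmax(ll)])


def max_matched_oracle(n_with_sd: int, n_failed: int, max_fraction: float) -> int:
    """Brute-force largest m with m/(n_with_sd+m) <= max_fraction."""
    best = 0
    for m in range(n_failed + 1):
        if m / (n_with_sd + m) <= max_fraction:
            best = m
    return best
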