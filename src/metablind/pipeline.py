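"""End-to-end pipeline: impute -> classify -> pool -> compare -> meta-regress.

Emits a stratum-comparison report and a moderator-model report (CSV),
forest-plot data (TSV — numbers never live only in a figure), the per-arm
imputation report, and a JSON run manifest from which any output can be
regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .blinding import (
    BlindingStatus,
    StratumComparison,
    classify_records,
    rob_domain_comparisons,
)
from .imputation import impute_trial_set
from .meta_regression import forward_stepwise, univariate_screen
from .pooling import Z95, arm_effect_inputs, pool_random
from .trial_data_io import ARMS_FILE, ROB_FILE, TRIALS_FILE, ArmRole, TrialRecord, read_trial_set

log = logging.getLogger("metablind")

#: Moderators screened univariately by default.
DEFAULT_UNIVARIATE_MODERATORS = (
    "naive_to_intervention",
    "pct_prior_experience",
    "baseline_severity",
    "disease_duration",
    "study_duration_weeks",
    "continent",
    "single_center",
    "commercial_funding",
    "pct_psychogenic",
    "prostate_or_sci",
    "n_followups",
    "pct_randomized_not_analyzed",
    "sample_size",
    "publication_year",
    "parallel_design",
    "drug",
)

#: Default forward-stepwise candidate pool (continuous/binary moderators).
DEFAULT_STEPWISE_CANDIDATES = (
    "naive_to_intervention",
    "pct_prior_experience",
    "baseline_severity",
    "disease_duration",
    "pct_randomized_not_analyzed",
    "sample_size",
    "publication_year",
)


@dataclass
class PipelineResult:
    outputs: dict[str, Path]
    manifest: dict
    table2: list[StratumComparison]
    summary_estimable: bool


def _g(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(x, ".6g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    max_matched_fraction: float = 0.33,
    p_enter: float = 0.15,
    candidates: Optional[Sequence[str]] = None,
    use_t: bool = False,
    make_plots: bool = False,
) -> PipelineResult:
    """Run every analysis stage on a validated trial set.

    Deterministic given the input files and ``seed``; rerunning with the
    same manifest settings reproduces every output byte-for-byte.
    """
    input_dir = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("[read] loading trial set from %s", input_dir)
    records = read_trial_set(input_dir)
    n_read = len(records)

    log.info("[impute] deriving change scores and SDs (seed=%d)", seed)
    records, reports = impute_trial_set(
        records, seed=seed, max_matched_fraction=max_matched_fraction
    )
    excluded_ids = {r.trial_id for r in reports if r.excluded}
    analysis = [rec for rec in records if rec.trial_id not in excluded_ids]
    log.info("[impute] %d/%d trials retained", len(analysis), n_read)

    report_frame = pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "arm_role": r.arm_role,
                "method": r.method,
                "donor_id": r.donor_id or "",
                "resulting_sd": _g(r.resulting_sd),
                "excluded": int(r.excluded),
                "note": r.note,
            }
            for r in reports
        ]
    )
    imputation_path = out / "imputation_report.csv"
    report_frame.to_csv(imputation_path, index=False)

    log.info("[classify] blinding status")
    strata = classify_records(analysis)
    counts = {s.value: len(strata[s]) for s in BlindingStatus}

    log.info("[compare] per-domain and summary stratum comparisons")
    table2_rows = []
    comparisons: list[StratumComparison] = []
    summary_estimable = True
    for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
        for cmp_row in rob_domain_comparisons(analysis, role, use_t=use_t):
            comparisons.append(cmp_row)
            if cmp_row.label == "summary" and not cmp_row.estimable:
                summary_estimable = False
            pa, pb = cmp_row.pooled_a, cmp_row.pooled_b
            table2_rows.append(
                {
                    "arm": role.value,
                    "comparison": cmp_row.label,
                    "k_low": pa.k if pa else "",
                    "n_low": pa.n_total if pa else "",
                    "k_other": pb.k if pb else "",
                    "n_other": pb.n_total if pb else "",
                    "mu_low": _g(pa.mu) if pa else "",
                    "ci_low_a": _g(pa.ci_low) if pa else "",
                    "ci_high_a": _g(pa.ci_high) if pa else "",
                    "i2_low": _g(pa.i2) if pa else "",
                    "mu_other": _g(pb.mu) if pb else "",
                    "ci_low_b": _g(pb.ci_low) if pb else "",
                    "ci_high_b": _g(pb.ci_high) if pb else "",
                    "i2_other": _g(pb.i2) if pb else "",
                    "difference": _g(cmp_row.d),
                    "diff_ci_low": _g(cmp_row.ci_low),
                    "diff_ci_high": _g(cmp_row.ci_high),
                    "z": _g(cmp_row.z),
                    "p": _g(cmp_row.p),
                    "relative_percent": (
                        str(round(cmp_row.relative_percent))
                        if cmp_row.relative_percent is not None
                        else ""
                    ),
                    "q_between": _g(cmp_row.q_between),
                    "p_between": _g(cmp_row.p_between),
                    "q_total": _g(cmp_row.q_total),
                    "estimable": int(cmp_row.estimable),
                    "note": cmp_row.note,
                }
            )
    table2_path = out / "table2.csv"
    pd.DataFrame(table2_rows).to_csv(table2_path, index=False)

    log.info("[forest] exporting per-study forest data")
    forest_paths: dict[str, Path] = {}
    for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
        rows = []
        for status in (BlindingStatus.ADEQUATE, BlindingStatus.INADEQUATE):
            stratum = strata[status]
            if not stratum:
                continue
            effects = arm_effect_inputs(stratum, role)
            pooled = pool_random(effects) if len(effects) > 1 else None
            for j, e in enumerate(effects):
                half = Z95 * math.sqrt(e.v)
                rows.append(
                    {
                        "stratum": status.value,
                        "trial_id": e.trial_id,
                        "y": _g(e.y),
                        "ci_low": _g(e.y - half),
                        "ci_high": _g(e.y + half),
                        "weight_pct": _g(100.0 * pooled.weights[j]) if pooled else "",
                    }
                )
        path = out / f"forest_{role.value}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        forest_paths[f"forest_{role.value}"] = path
        if make_plots:
            _render_forest(rows, role.value, out / f"forest_{role.value}.png")

    log.info("[metareg] univariate screen and forward-stepwise models")
    table3_rows = []
    cand = list(candidates) if candidates is not None else list(DEFAULT_STEPWISE_CANDIDATES)
    for role in (ArmRole.PLACEBO, ArmRole.INTERVENTION):
        for res in univariate_screen(analysis, role, DEFAULT_UNIVARIATE_MODERATORS):
            if not res.estimable:
                table3_rows.append(
                    {
                        "section": "univariate",
                        "arm": role.value,
                        "moderator": res.moderator,
                        "term": "",
                        "k": "",
                        "beta": "",
                        "se": "",
                        "p": "",
                        "beta_std": "",
                        "r2_explained": "",
                        "note": res.note,
                    }
                )
                continue
            for term in res.terms:
                if term.name == "intercept":
                    continue
                table3_rows.append(
                    {
                        "section": "univariate",
                        "arm": role.value,
                        "moderator": res.moderator,
                        "term": term.name,
                        "k": res.k,
                        "beta": _g(term.beta),
                        "se": _g(term.se),
                        "p": _g(term.p),
                        "beta_std": _g(term.beta_std),
                        "r2_explained": _g(res.r2_explained),
                        "note": "",
                    }
                )
        role_cand = cand + (["placebo_effect"] if role is ArmRole.INTERVENTION else [])
        multi = forward_stepwise(analysis, role, role_cand, p_enter=p_enter)
        for term in multi.terms:
            table3_rows.append(
                {
                    "section": "multivariate",
                    "arm": role.value,
                    "moderator": multi.moderator,
                    "term": term.name,
                    "k": multi.k,
                    "beta": _g(term.beta),
                    "se": _g(term.se),
                    "p": _g(term.p),
                    "beta_std": _g(term.beta_std),
                    "r2_explained": _g(multi.r2_explained),
                    "note": "entry order: " + (", ".join(multi.entry_order) or "none"),
                }
            )
    table3_path = out / "table3.csv"
    pd.DataFrame(table3_rows).to_csv(table3_path, index=False)

    method_counts: dict[str, int] = {}
    for r in reports:
        method_counts[r.method] = method_counts.get(r.method, 0) + 1
    manifest = {
        "pipeline_version": __version__,
        "inputs": {
            name: _digest(input_dir / name) for name in (TRIALS_FILE, ARMS_FILE, ROB_FILE)
        },
        "seed": seed,
        "config": {
            "max_matched_fraction": max_matched_fraction,
            "p_enter": p_enter,
            "candidates": cand,
            "use_t": use_t,
        },
        "counts": {
            "read": n_read,
            "excluded": len(excluded_ids),
            "retained": len(analysis),
            "by_blinding_status": counts,
            "imputation_methods": dict(sorted(method_counts.items())),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    outputs = {
        "table2": table2_path,
        "table3": table3_path,
        "imputation_report": imputation_path,
        "manifest": manifest_path,
        **forest_paths,
    }
    return PipelineResult(
        outputs=outputs,
        manifest=manifest,
        table2=comparisons,
        summary_estimable=summary_estimable,
    )


def _render_forest(rows: list[dict], arm: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(rows))))
    for i, row in enumerate(reversed(rows)):
        y = float(row["y"])
        lo, hi = float(row["ci_low"]), float(row["ci_high"])
        ax.plot([lo, hi], [i, i], color="k", lw=1)
        ax.plot([y], [i], "s", color="k", ms=4)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r["trial_id"] for r in reversed(rows)], fontsize=6)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"IIEF-EF change ({arm} arms)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
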