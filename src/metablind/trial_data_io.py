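"""Study-level data model and CSV schema for blinding meta-epidemiology.

A trial set is a directory of three relational CSV files joined on
``trial_id``:

* ``trials.csv`` — one row per trial: design, drug, publication year and
  the moderator covariates (controlled vocabulary).
* ``arms.csv`` — two rows per trial (placebo, intervention): sample sizes,
  baseline/final/change means on the IIEF-EF scale and whatever variability
  statistic the source reported (SD, SE, 95% CI, t or P).
* ``rob.csv`` — one row per trial: Cochrane risk-of-bias judgments for the
  four blinding-related domains plus auxiliary domains.

Missing values are empty cells; the literal string ``NA`` is also accepted
on read.  Risk-of-bias levels are normalized case- and whitespace-
insensitively; ``unknown`` maps to ``unclear`` (see ``ROB_NORMALIZATION``).
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator


class SchemaError(ValueError):
    """A trial-set file or required column is missing or unreadable."""


class TrialSetValidationError(ValueError):
    """One or more rows violate the data-model invariants.

    Every offending row yields its own diagnostic string in
    :attr:`diagnostics`; nothing is silently coerced.
    """

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "trial set failed validation:\n" + "\n".join(f"  - {d}" for d in self.diagnostics)
        )


class ArmRole(str, Enum):
    PLACEBO = "placebo"
    INTERVENTION = "intervention"


class Design(str, Enum):
    PARALLEL = "parallel"
    CROSSOVER = "crossover"


class Drug(str, Enum):
    SILDENAFIL = "sildenafil"
    VARDENAFIL = "vardenafil"
    TADALAFIL = "tadalafil"
    OTHER = "other"


class ROBLevel(str, Enum):
    LOW = "low"
    UNCLEAR = "unclear"
    HIGH = "high"


#: Exhaustive normalization table for risk-of-bias levels.  Keys are the
#: stripped, lower-cased cell contents; anything else is a validation error.
ROB_NORMALIZATION: dict[str, ROBLevel] = {
    "low": ROBLevel.LOW,
    "unclear": ROBLevel.UNCLEAR,
    "high": ROBLevel.HIGH,
    "unknown": ROBLevel.UNCLEAR,
}


def normalize_rob_level(raw: object) -> ROBLevel:
    """Map a raw cell value to a :class:`ROBLevel` per ``ROB_NORMALIZATION``."""
    if isinstance(raw, ROBLevel):
        return raw
    key = str(raw).strip().lower()
    try:
        return ROB_NORMALIZATION[key]
    except KeyError:
        raise ValueError(f"unknown risk-of-bias level {raw!r}") from None


CONTINENTS = (
    "across",
    "africa",
    "asia",
    "europe",
    "north_america",
    "oceania",
    "south_america",
)

#: Controlled moderator vocabulary and value types.
MODERATOR_TYPES: dict[str, type] = {
    "naive_to_intervention": bool,
    "pct_prior_experience": float,
    "baseline_severity": float,
    "disease_duration": float,
    "study_duration_weeks": float,
    "continent": str,
    "single_center": bool,
    "commercial_funding": bool,
    "pct_psychogenic": float,
    "prostate_or_sci": bool,
    "n_followups": int,
    "pct_randomized_not_analyzed": float,
}
MODERATOR_ORDER = tuple(MODERATOR_TYPES)


class ArmSummary(BaseModel):
    """One trial arm's sample sizes, change-score summary and variability.

    ``change_mean`` is the within-arm change from baseline (final − baseline)
    in IIEF-EF points; any of the variability statistics may be absent.
    """

    model_config = ConfigDict(frozen=True)

    arm_role: ArmRole
    n_randomized: int = Field(gt=0)
    n_analyzed: int = Field(gt=0)
    baseline_mean: Optional[float] = Field(default=None, allow_inf_nan=False)
    final_mean: Optional[float] = Field(default=None, allow_inf_nan=False)
    change_mean: Optional[float] = Field(default=None, allow_inf_nan=False)
    sd_change: Optional[float] = Field(default=None, gt=0, allow_inf_nan=False)
    se: Optional[float] = Field(default=None, gt=0, allow_inf_nan=False)
    ci_low: Optional[float] = Field(default=None, allow_inf_nan=False)
    ci_high: Optional[float] = Field(default=None, allow_inf_nan=False)
    t_value: Optional[float] = Field(default=None, allow_inf_nan=False)
    p_value: Optional[float] = Field(default=None, gt=0, le=1)
    # True when the source reported an inequality ("<0.05"); the value is
    # stored at the bound and downstream imputation treats it conservatively.
    p_is_bound: bool = False
    geq_responders: Optional[int] = Field(default=None, ge=0)
    ae_headache: Optional[int] = Field(default=None, ge=0)
    ae_flushing: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_invariants(self) -> "ArmSummary":
        if self.n_analyzed > self.n_randomized:
            raise ValueError(
                f"n_analyzed ({self.n_analyzed}) exceeds n_randomized ({self.n_randomized})"
            )
        for name in ("geq_responders", "ae_headache", "ae_flushing"):
            value = getattr(self, name)
            if value is not None and value > self.n_randomized:
                raise ValueError(f"{name} ({value}) exceeds n_randomized ({self.n_randomized})")
        if self.ci_low is not None and self.ci_high is not None and self.ci_low > self.ci_high:
            raise ValueError(f"ci_low ({self.ci_low}) exceeds ci_high ({self.ci_high})")
        if self.p_is_bound and self.p_value is None:
            raise ValueError("p_is_bound requires a p_value")
        return self


class ROBAssessment(BaseModel):
    """Cochrane risk-of-bias judgments for one trial.

    The four blinding-related domains are mandatory; auxiliary domains
    (sequence generation, ITT, baseline balance) are carried alongside.
    """

    model_config = ConfigDict(frozen=True)

    allocation_concealment: ROBLevel
    blinding_participant: ROBLevel
    blinding_caregiver: ROBLevel
    blinding_assessor: ROBLevel
    sequence_generation: ROBLevel = ROBLevel.UNCLEAR
    itt_analysis: bool = False
    baseline_balanced: bool = True

    @field_validator(
        "allocation_concealment",
        "blinding_participant",
        "blinding_caregiver",
        "blinding_assessor",
        "sequence_generation",
        mode="before",
    )
    @classmethod
    def _normalize(cls, v: object) -> ROBLevel:
        return normalize_rob_level(v)


#: Names of the four blinding-related domains, in canonical order.
BLINDING_DOMAINS = (
    "allocation_concealment",
    "blinding_participant",
    "blinding_caregiver",
    "blinding_assessor",
)


class TrialRecord(BaseModel):
    """A trial: two arm summaries, a risk-of-bias assessment and moderators."""

    model_config = ConfigDict(frozen=True)

    trial_id: str = Field(min_length=1)
    design: Design
    drug: Drug
    publication_year: int = Field(ge=1900, le=2100)
    placebo_arm: ArmSummary
    intervention_arm: ArmSummary
    rob: ROBAssessment
    moderators: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "TrialRecord":
        if self.placebo_arm.arm_role is not ArmRole.PLACEBO:
            raise ValueError("placebo_arm must have arm_role 'placebo'")
        if self.intervention_arm.arm_role is not ArmRole.INTERVENTION:
            raise ValueError("intervention_arm must have arm_role 'intervention'")
        for name, value in self.moderators.items():
            if name not in MODERATOR_TYPES:
                raise ValueError(f"unknown moderator {name!r}")
            expected = MODERATOR_TYPES[name]
            if expected is float and isinstance(value, int) and not isinstance(value, bool):
                value = float(value)
                self.moderators[name] = value
            if not isinstance(value, expected) or (expected is not bool and isinstance(value, bool)):
                raise ValueError(
                    f"moderator {name!r} expects {expected.__name__}, got {type(value).__name__}"
                )
            if expected is float and not math.isfinite(value):
                raise ValueError(f"moderator {name!r} must be finite")
            if name == "continent" and value not in CONTINENTS:
                raise ValueError(f"continent {value!r} not one of {CONTINENTS}")
        return self

    def arm(self, role: ArmRole | str) -> ArmSummary:
        role = ArmRole(role)
        return self.placebo_arm if role is ArmRole.PLACEBO else self.intervention_arm

    def with_arm(self, arm: ArmSummary) -> "TrialRecord":
        """Return a copy with the arm of ``arm.arm_role`` replaced."""
        if arm.arm_role is ArmRole.PLACEBO:
            return self.model_copy(update={"placebo_arm": arm})
        return self.model_copy(update={"intervention_arm": arm})


# --------------------------------------------------------------------------
# CSV schema
# --------------------------------------------------------------------------

TRIALS_FILE = "trials.csv"
ARMS_FILE = "arms.csv"
ROB_FILE = "rob.csv"

TRIAL_COLUMNS = ("trial_id", "design", "drug", "publication_year") + MODERATOR_ORDER
ARM_COLUMNS = (
    "trial_id",
    "arm_role",
    "n_randomized",
    "n_analyzed",
    "baseline_mean",
    "final_mean",
    "change_mean",
    "sd_change",
    "se",
    "ci_low",
    "ci_high",
    "t_value",
    "p_value",
    "geq_responders",
    "ae_headache",
    "ae_flushing",
)
ROB_COLUMNS = ("trial_id",) + BLINDING_DOMAINS + (
    "sequence_generation",
    "itt_analysis",
    "baseline_balanced",
)

#: Machine-readable column dictionary (exported by :func:`write_schema_json`).
COLUMN_SCHEMA: dict[str, dict[str, dict[str, str]]] = {
    TRIALS_FILE: {
        "trial_id": {"type": "string", "description": "unique trial identifier"},
        "design": {"type": "enum:parallel|crossover", "description": "trial design"},
        "drug": {
            "type": "enum:sildenafil|vardenafil|tadalafil|other",
            "description": "PDE-5 inhibitor studied",
        },
        "publication_year": {"type": "int", "description": "year of publication"},
        **{
            name: {
                "type": {bool: "bool(0/1)", float: "float", int: "int", str: "string"}[typ],
                "description": f"moderator covariate ({name})",
            }
            for name, typ in MODERATOR_TYPES.items()
        },
    },
    ARMS_FILE: {
        "trial_id": {"type": "string", "description": "foreign key into trials.csv"},
        "arm_role": {"type": "enum:placebo|intervention", "description": "arm role"},
        "n_randomized": {"type": "int", "description": "participants randomized to the arm"},
        "n_analyzed": {"type": "int", "description": "participants analyzed"},
        "baseline_mean": {"type": "float", "description": "baseline IIEF-EF mean"},
        "final_mean": {"type": "float", "description": "final IIEF-EF mean"},
        "change_mean": {"type": "float", "description": "mean change (final - baseline)"},
        "sd_change": {"type": "float", "description": "SD of the change score"},
        "se": {"type": "float", "description": "standard error of the mean change"},
        "ci_low": {"type": "float", "description": "95% CI lower bound of the mean change"},
        "ci_high": {"type": "float", "description": "95% CI upper bound of the mean change"},
        "t_value": {"type": "float", "description": "t statistic of the mean change"},
        "p_value": {"type": "float", "description": "two-sided P ('<x' accepted, stored at bound)"},
        "geq_responders": {"type": "int", "description": "Global Efficacy Question responders"},
        "ae_headache": {"type": "int", "description": "participants reporting headache"},
        "ae_flushing": {"type": "int", "description": "participants reporting flushing"},
    },
    ROB_FILE: {
        "trial_id": {"type": "string", "description": "foreign key into trials.csv"},
        **{
            d: {"type": "enum:low|unclear|high", "description": f"risk-of-bias judgment: {d}"}
            for d in BLINDING_DOMAINS + ("sequence_generation",)
        },
        "itt_analysis": {"type": "bool(0/1)", "description": "intention-to-treat analysis"},
        "baseline_balanced": {"type": "bool(0/1)", "description": "baseline prognostic balance"},
    },
}


def write_schema_json(path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(COLUMN_SCHEMA, indent=2, sort_keys=True) + "\n")
    return path


# --------------------------------------------------------------------------
# serialization helpers (missing value convention: empty cell, 'NA' accepted)
# --------------------------------------------------------------------------

_MISSING = {"", "NA"}


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(cell: str) -> Optional[float]:
    if cell in _MISSING:
        return None
    return float(cell)


def _parse_int(cell: str) -> Optional[int]:
    if cell in _MISSING:
        return None
    return int(cell)


def _parse_bool(cell: str) -> Optional[bool]:
    if cell in _MISSING:
        return None
    key = cell.strip().lower()
    if key in {"1", "true", "yes"}:
        return True
    if key in {"0", "false", "no"}:
        return False
    raise ValueError(f"cannot interpret {cell!r} as a flag")


def _read_csv(path: Path, required_columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing trial-set file: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return frame


def read_trial_set(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial set from a directory of three CSV files.

    Raises :class:`SchemaError` for structural problems (missing file or
    column) and :class:`TrialSetValidationError` with per-row diagnostics
    for records that violate the data-model invariants.
    """
    root = Path(path)
    trials = _read_csv(root / TRIALS_FILE, ("trial_id", "design", "drug", "publication_year"))
    arms = _read_csv(root / ARMS_FILE, ARM_COLUMNS)
    rob = _read_csv(root / ROB_FILE, ("trial_id",) + BLINDING_DOMAINS)

    diagnostics: list[str] = []

    arm_map: dict[str, dict[str, ArmSummary]] = {}
    for i, row in arms.iterrows():
        tid = row["trial_id"]
        label = f"{ARMS_FILE} row {i + 2} (trial {tid!r})"
        try:
            p_cell = str(row["p_value"]).strip()
            p_is_bound = p_cell.startswith("<")
            p_value = _parse_float(p_cell.lstrip("<"))
            arm = ArmSummary(
                arm_role=row["arm_role"].strip().lower(),
                n_randomized=_parse_int(row["n_randomized"]),
                n_analyzed=_parse_int(row["n_analyzed"]),
                baseline_mean=_parse_float(row["baseline_mean"]),
                final_mean=_parse_float(row["final_mean"]),
                change_mean=_parse_float(row["change_mean"]),
                sd_change=_parse_float(row["sd_change"]),
                se=_parse_float(row["se"]),
                ci_low=_parse_float(row["ci_low"]),
                ci_high=_parse_float(row["ci_high"]),
                t_value=_parse_float(row["t_value"]),
                p_value=p_value,
                p_is_bound=p_is_bound,
                geq_responders=_parse_int(row["geq_responders"]),
                ae_headache=_parse_int(row["ae_headache"]),
                ae_flushing=_parse_int(row["ae_flushing"]),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            diagnostics.append(f"{label}: {_brief(exc)}")
            continue
        slot = arm_map.setdefault(tid, {})
        if arm.arm_role.value in slot:
            diagnostics.append(f"{label}: duplicate {arm.arm_role.value} arm")
        else:
            slot[arm.arm_role.value] = arm

    rob_map: dict[str, ROBAssessment] = {}
    for i, row in rob.iterrows():
        tid = row["trial_id"]
        label = f"{ROB_FILE} row {i + 2} (trial {tid!r})"
        if tid in rob_map:
            diagnostics.append(f"{label}: duplicate risk-of-bias row")
            continue
        try:
            rob_map[tid] = ROBAssessment(
                allocation_concealment=row["allocation_concealment"],
                blinding_participant=row["blinding_participant"],
                blinding_caregiver=row["blinding_caregiver"],
                blinding_assessor=row["blinding_assessor"],
                sequence_generation=row.get("sequence_generation", "unclear") or "unclear",
                itt_analysis=_parse_bool(row.get("itt_analysis", "0") or "0"),
                baseline_balanced=_parse_bool(row.get("baseline_balanced", "1") or "1"),
            )
        except (ValidationError, ValueError) as exc:
            diagnostics.append(f"{label}: {_brief(exc)}")

    records: list[TrialRecord] = []
    seen: set[str] = set()
    for i, row in trials.iterrows():
        tid = row["trial_id"]
        label = f"{TRIALS_FILE} row {i + 2} (trial {tid!r})"
        if tid in seen:
            diagnostics.append(f"{label}: duplicate trial_id")
            continue
        seen.add(tid)
        arms_here = arm_map.get(tid, {})
        if set(arms_here) != {"placebo", "intervention"}:
            diagnostics.append(
                f"{label}: expected one placebo and one intervention arm, found {sorted(arms_here)}"
            )
            continue
        if tid not in rob_map:
            diagnostics.append(f"{label}: no risk-of-bias row")
            continue
        moderators: dict[str, Any] = {}
        try:
            for name, typ in MODERATOR_TYPES.items():
                cell = str(row.get(name, "")).strip()
                if cell in _MISSING:
                    continue
                if typ is bool:
                    moderators[name] = _parse_bool(cell)
                elif typ is int:
                    moderators[name] = _parse_int(cell)
                elif typ is float:
                    moderators[name] = _parse_float(cell)
                else:
                    moderators[name] = cell
            records.append(
                TrialRecord(
                    trial_id=tid,
                    design=row["design"].strip().lower(),
                    drug=row["drug"].strip().lower(),
                    publication_year=_parse_int(row["publication_year"]),
                    placebo_arm=arms_here["placebo"],
                    intervention_arm=arms_here["intervention"],
                    rob=rob_map[tid],
                    moderators=moderators,
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            diagnostics.append(f"{label}: {_brief(exc)}")

    if diagnostics:
        raise TrialSetValidationError(diagnostics)
    return records


def _brief(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        parts = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "record"
            parts.append(f"{loc}: {err['msg']}")
        return "; ".join(parts)
    return str(exc)


def write_trial_set(records: list[TrialRecord], path: str | Path) -> Path:
    """Write a trial set to ``path`` (created if needed); round-trips exactly.

    Floats are written with full ``repr`` precision so that
    ``read_trial_set(write_trial_set(X)) == X`` for every valid set.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    trial_rows = []
    arm_rows = []
    rob_rows = []
    for rec in records:
        trial_rows.append(
            [_fmt(rec.trial_id), _fmt(rec.design), _fmt(rec.drug), _fmt(rec.publication_year)]
            + [_fmt(rec.moderators.get(name)) for name in MODERATOR_ORDER]
        )
        for arm in (rec.placebo_arm, rec.intervention_arm):
            p_cell = _fmt(arm.p_value)
            if arm.p_is_bound and p_cell:
                p_cell = "<" + p_cell
            arm_rows.append(
                [
                    _fmt(rec.trial_id),
                    _fmt(arm.arm_role),
                    _fmt(arm.n_randomized),
                    _fmt(arm.n_analyzed),
                    _fmt(arm.baseline_mean),
                    _fmt(arm.final_mean),
                    _fmt(arm.change_mean),
                    _fmt(arm.sd_change),
                    _fmt(arm.se),
                    _fmt(arm.ci_low),
                    _fmt(arm.ci_high),
                    _fmt(arm.t_value),
                    p_cell,
                    _fmt(arm.geq_responders),
                    _fmt(arm.ae_headache),
                    _fmt(arm.ae_flushing),
                ]
            )
        r = rec.rob
        rob_rows.append(
            [
                _fmt(rec.trial_id),
                _fmt(r.allocation_concealment),
                _fmt(r.blinding_participant),
                _fmt(r.blinding_caregiver),
                _fmt(r.blinding_assessor),
                _fmt(r.sequence_generation),
                _fmt(r.itt_analysis),
                _fmt(r.baseline_balanced),
            ]
        )

    pd.DataFrame(trial_rows, columns=list(TRIAL_COLUMNS)).to_csv(root / TRIALS_FILE, index=False)
    pd.DataFrame(arm_rows, columns=list(ARM_COLUMNS)).to_csv(root / ARMS_FILE, index=False)
    pd.DataFrame(rob_rows, columns=list(ROB_COLUMNS)).to_csv(root / ROB_FILE, index=False)
    return root
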