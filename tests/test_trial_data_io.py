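"""Data model, CSV round-trip and validation diagnostics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from metablind import (
    ArmSummary,
    ROBAssessment,
    ROBLevel,
    TrialRecord,
    read_trial_set,
    write_trial_set,
)
from metablind.trial_data_io import (
    ARMS_FILE,
    ROB_NORMALIZATION,
    SchemaError,
    TrialSetValidationError,
    normalize_rob_level,
)

from helpers import make_arm, make_record


finite = st.floats(allow_nan=False, allow_infinity=False, min_value=-50, max_value=50)
positive = st.floats(min_value=0.01, max_value=30, allow_nan=False)


@st.composite
def arm_summaries(draw, role):
    n_rand = draw(st.integers(min_value=2, max_value=500))
    n_anal = draw(st.integers(min_value=1, max_value=n_rand))
    ci = draw(st.none() | st.tuples(finite, positive))
    return ArmSummary(
        arm_role=role,
        n_randomized=n_rand,
        n_analyzed=n_anal,
        baseline_mean=draw(st.none() | finite),
        final_mean=draw(st.none() | finite),
        change_mean=draw(st.none() | finite),
        sd_change=draw(st.none() | positive),
        se=draw(st.none() | positive),
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[0] + ci[1],
        t_value=draw(st.none() | finite),
        p_value=(p := draw(st.none() | st.floats(min_value=1e-6, max_value=1.0,
                                                 allow_nan=False))),
        p_is_bound=draw(st.booleans()) if p is not None else False,
        geq_responders=draw(st.none() | st.integers(min_value=0, max_value=n_rand)),
        ae_headache=draw(st.none() | st.integers(min_value=0, max_value=n_rand)),
        ae_flushing=draw(st.none() | st.integers(min_value=0, max_value=n_rand)),
    )


levels = st.sampled_from(["low", "unclear", "high"])


@st.composite
def trial_records(draw, tid):
    moderators = {}
    if draw(st.booleans()):
        moderators["baseline_severity"] = draw(positive)
    if draw(st.booleans()):
        moderators["naive_to_intervention"] = draw(st.booleans())
    if draw(st.booleans()):
        moderators["continent"] = draw(st.sampled_from(["asia", "europe", "north_america"]))
    if draw(st.booleans()):
        moderators["n_followups"] = draw(st.integers(min_value=1, max_value=6))
    return TrialRecord(
        trial_id=tid,
        design=draw(st.sampled_from(["parallel", "crossover"])),
        drug=draw(st.sampled_from(["sildenafil", "vardenafil", "tadalafil", "other"])),
        publication_year=draw(st.integers(min_value=1998, max_value=2012)),
        placebo_arm=draw(arm_summaries("placebo")),
        intervention_arm=draw(arm_summaries("intervention")),
        rob=ROBAssessment(
            allocation_concealment=draw(levels),
            blinding_participant=draw(levels),
            blinding_caregiver=draw(levels),
            blinding_assessor=draw(levels),
            sequence_generation=draw(levels),
            itt_analysis=draw(st.booleans()),
            baseline_balanced=draw(st.booleans()),
        ),
        moderators=moderators,
    )


@st.composite
def trial_sets(draw):
    k = draw(st.integers(min_value=0, max_value=6))
    return [draw(trial_records(f"T{i:03d}")) for i in range(k)]


@settings(max_examples=25, derandomize=True, deadline=None)
@given(trial_sets())
def test_round_trip_identity(tmp_path_factory, records):
    """read(write(X)) == X for every valid trial set, including empty ones."""
    path = tmp_path_factory.mktemp("ts")
    write_trial_set(records, path)
    assert read_trial_set(path) == records


def test_missing_values_round_trip_as_absent(tmp_path):
    rec = make_record("T001", placebo=make_arm("placebo", sd=None),
                      intervention=make_arm("intervention", change=9.0))
    write_trial_set([rec], tmp_path)
    back = read_trial_set(tmp_path)
    assert back[0].placebo_arm.sd_change is None
    assert back == [rec]


def test_na_string_accepted_as_missing(tmp_path):
    rec = make_record("T001")
    write_trial_set([rec], tmp_path)
    arms = (tmp_path / ARMS_FILE).read_text().replace("T001,placebo,100,100,,",
                                                      "T001,placebo,100,100,NA,")
    (tmp_path / ARMS_FILE).write_text(arms)
    assert read_trial_set(tmp_path)[0].placebo_arm.baseline_mean is None


@pytest.mark.parametrize(
    "raw,expected",
    [(key, lvl) for key, lvl in ROB_NORMALIZATION.items()]
    + [("Low ", ROBLevel.LOW), (" UNCLEAR", ROBLevel.UNCLEAR), ("High", ROBLevel.HIGH),
       ("  unknown  ", ROBLevel.UNCLEAR), ("LOW", ROBLevel.LOW)],
)
def test_rob_level_normalization(raw, expected):
    """Case/whitespace variants of the documented table all normalize."""
    assert normalize_rob_level(raw) is expected


@pytest.mark.parametrize("raw", ["lo", "moderate", "", "yes"])
def test_rob_level_rejects_unknown(raw):
    with pytest.raises(ValueError):
        normalize_rob_level(raw)


def test_validation_error_names_offending_row(tmp_path):
    rec = make_record("T001")
    write_trial_set([rec], tmp_path)
    arms = (tmp_path / ARMS_FILE).read_text().replace("T001,placebo,100,100",
                                                      "T001,placebo,100,150")
    (tmp_path / ARMS_FILE).write_text(arms)
    with pytest.raises(TrialSetValidationError) as err:
        read_trial_set(tmp_path)
    assert any("T001" in d and "n_analyzed" in d for d in err.value.diagnostics)


def test_duplicate_trial_id_rejected(tmp_path):
    rec = make_record("T001")
    write_trial_set([rec], tmp_path)
    trials = tmp_path / "trials.csv"
    lines = trials.read_text().splitlines()
    trials.write_text("\n".join(lines + [lines[1]]) + "\n")
    with pytest.raises(TrialSetValidationError, match="duplicate trial_id"):
        read_trial_set(tmp_path)


def test_missing_column_is_schema_error(tmp_path):
    import pandas as pd

    write_trial_set([make_record("T001")], tmp_path)
    arms = tmp_path / ARMS_FILE
    pd.read_csv(arms).drop(columns=["sd_change"]).to_csv(arms, index=False)
    with pytest.raises(SchemaError, match="sd_change"):
        read_trial_set(tmp_path)


def test_p_value_bound_round_trips(tmp_path):
    arm = make_arm("placebo", sd=None, p_value=0.05, p_is_bound=True)
    rec = make_record("T001", placebo=arm)
    write_trial_set([rec], tmp_path)
    assert "<0.05" in (tmp_path / ARMS_FILE).read_text()
    back = read_trial_set(tmp_path)
    assert back[0].placebo_arm.p_is_bound and back[0].placebo_arm.p_value == 0.05


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_randomized": 50, "n_analyzed": 60},
        {"geq_responders": 200},
        {"ci_low": 3.0, "ci_high": 1.0},
        {"p_value": 1.5},
        {"p_value": 0.0},
        {"sd_change": -1.0},
    ],
)
def test_arm_invariants_rejected(kwargs):
    base = dict(arm_role="placebo", n_randomized=100, n_analyzed=100)
    base.update(kwargs)
    with pytest.raises(ValidationError):
        ArmSummary(**base)


def test_unknown_moderator_rejected():
    with pytest.raises(ValidationError, match="unknown moderator"):
        make_record("T001", moderators={"astrological_sign": 1.0})
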