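"""REML weighted meta-regression: tau2 estimation, screening, stepwise."""

import numpy as np
import pytest

from metablind import pool_random, reml_meta_regress, univariate_screen
from metablind.meta_regression import (
    CollinearityError,
    RegressionError,
    forward_stepwise,
)
from metablind.pooling import EffectInput
from metablind.synthetic_data import GeneratorConfig, generate_trial_set

from helpers import make_arm, make_record, reml_grid_oracle


def _fit(y, v, x, **kw):
    X = np.column_stack([np.ones(len(y)), x])
    return reml_meta_regress(y, v, X, ["intercept", "x"], **kw)


class TestREML:
    def test_noiseless_linear_relation(self):
        x = np.arange(8.0)
        y = 1.0 + 0.5 * x
        res = _fit(y, np.full(8, 0.04), x)
        assert res.tau2_res == pytest.approx(0.0, abs=1e-8)
        assert res.terms[1].beta == pytest.approx(0.5, abs=1e-8)
        assert res.r2_explained == pytest.approx(100.0)

    def test_intercept_only_matches_dl_when_homogeneous(self):
        """With Q <= df both DL and REML put tau2 at 0, so the weighted
        intercept equals the random-effects pooled mean."""
        y = [1.4, 1.5, 1.6, 1.5]
        v = [0.3, 0.4, 0.5, 0.35]
        pooled = pool_random([EffectInput(str(i), yi, vi) for i, (yi, vi) in
                              enumerate(zip(y, v))])
        assert pooled.tau2 == 0.0
        res = reml_meta_regress(y, v, np.ones((4, 1)), ["intercept"])
        assert res.tau2_res == pytest.approx(0.0, abs=1e-10)
        assert res.terms[0].beta == pytest.approx(pooled.mu, abs=1e-6)

    def test_tau2_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = 8
            x = rng.normal(size=k)
            v = rng.uniform(0.05, 0.5, k)
            tau = rng.uniform(0.0, 1.5)
            y = 1.0 + 0.5 * x + rng.normal(0, np.sqrt(v + tau ** 2))
            res = _fit(y, v, x)
            X = np.column_stack([np.ones(k), x])
            tau2_grid = reml_grid_oracle(y, v, X)
            assert res.tau2_res == pytest.approx(tau2_grid, abs=2e-4)
            assert res.converged

    def test_collinear_design_names_columns(self):
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(CollinearityError) as err:
            reml_meta_regress(np.ones(6), np.full(6, 0.1), X, ["intercept", "x", "x2"])
        assert "x2" in err.value.columns

    def test_needs_more_studies_than_coefficients(self):
        with pytest.raises(RegressionError):
            _fit([1.0, 2.0], [0.1, 0.1], [0.0, 1.0])

    def test_r2_invariant_to_affine_moderator_rescaling(self):
        rng = np.random.default_rng(3)
        k = 12
        x = rng.normal(size=k)
        v = rng.uniform(0.05, 0.3, k)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.5, k)
        a = _fit(y, v, x)
        b = _fit(y, v, 100.0 * x - 7.0)
        assert a.r2_explained == pytest.approx(b.r2_explained, abs=1e-5)
        assert a.terms[1].beta_std == pytest.approx(b.terms[1].beta_std, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        k = 10
        x = rng.normal(size=k)
        v = rng.uniform(0.05, 0.3, k)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.5, k)
        perm = rng.permutation(k)
        a = _fit(y, v, x)
        b = _fit(y[perm], v[perm], x[perm])
        assert a.tau2_res == pytest.approx(b.tau2_res, abs=1e-8)
        assert a.terms[1].beta == pytest.approx(b.terms[1].beta, abs=1e-8)


def _moderated_records(k, beta_naive, seed, naive_prob=0.5):
    cfg = GeneratorConfig(
        k_adequate=k, k_inadequate=0, seed=seed,
        moderator_effects={"naive_to_intervention": beta_naive},
        naive_prob=naive_prob, missing_sd_prob=0.0, final_only_prob=0.0,
    )
    return generate_trial_set(cfg)


class TestScreen:
    def test_binary_moderator_sign_recovery(self):
        res = univariate_screen(_moderated_records(60, 2.9, seed=5), "placebo",
                                ["naive_to_intervention"])[0]
        assert res.estimable
        assert res.terms[1].beta_std > 0

    def test_unobserved_moderator_not_estimable(self):
        recs = [make_record(f"T{i}") for i in range(5)]
        res = univariate_screen(recs, "placebo", ["pct_psychogenic"])[0]
        assert not res.estimable and "not estimable" in res.note

    def test_categorical_expansion_drops_reference(self):
        recs = []
        for i, cont in enumerate(["asia", "europe", "north_america", "across"] * 3):
            recs.append(make_record(f"T{i:02d}",
                                    placebo=make_arm("placebo", change=1.5 + 0.05 * i),
                                    moderators={"continent": cont}))
        res = univariate_screen(recs, "placebo", ["continent"])[0]
        names = [t.name for t in res.terms]
        assert names == ["intercept", "continent[across]", "continent[asia]",
                         "continent[europe]"]  # north_america is the reference


class TestStepwise:
    def test_strong_candidate_enters_null_does_not(self):
        recs = _moderated_records(60, 3.0, seed=9)
        res = forward_stepwise(recs, "placebo",
                               ["naive_to_intervention", "disease_duration"],
                               p_enter=0.15)
        assert "naive_to_intervention" in res.entry_order
        assert "disease_duration" not in res.entry_order

    def test_zero_entry_threshold_returns_intercept_only(self):
        recs = _moderated_records(30, 3.0, seed=9)
        res = forward_stepwise(recs, "placebo", ["naive_to_intervention"], p_enter=0.0)
        assert res.entry_order == []
        assert [t.name for t in res.terms] == ["intercept"]

    def test_entry_respects_smallest_p_first(self):
        """The stepwise trace equals an exhaustive re-computation of the
        smallest-p-first rule on the same records."""
        recs = _moderated_records(50, 2.5, seed=13)
        candidates = ["naive_to_intervention", "baseline_severity",
                      "pct_randomized_not_analyzed"]
        res = forward_stepwise(recs, "placebo", candidates, p_enter=0.5)

        # independent trace
        from metablind.meta_regression import _design_for
        selected = []
        remaining = list(candidates)
        while remaining:
            ps = {}
            for cand in remaining:
                y, v, X, names, _ = _design_for(recs, selected + [cand], "placebo")
                fit = reml_meta_regress(y, v, X, names)
                ps[cand] = min(t.p for t in fit.terms if t.name == cand)
            best = min(ps, key=ps.get)
            if ps[best] >= 0.5:
                break
            selected.append(best)
            remaining.remove(best)
        assert res.entry_order == selected


class TestParameterRecovery:
    def test_moderator_effect_recovered_across_replicates(self):
        """Mean fitted coefficient over 200 synthetic sets (k = 40) covers
        the generating effect within Monte-Carlo error and has its sign."""
        betas = []
        for rep in range(200):
            recs = _moderated_records(40, 2.9, seed=1000 + rep)
            res = univariate_screen(recs, "placebo", ["naive_to_intervention"])[0]
            betas.append(res.terms[1].beta)
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert betas.mean() > 0
        assert abs(betas.mean() - 2.9) < 4 * mc_se
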