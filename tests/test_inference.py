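"""Panel likelihood, ML fitting, covariate effects, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from ciafmsm.cohort import CohortConfig, generate_cohort
from ciafmsm.ctmc import build_intensity_matrix
from ciafmsm.inference import (MultiStateMarkovModel, TransitionModel,
                               apply_covariates, bootstrap_derived, fit_msm,
                               panel_loglikelihood, prepare_panel,
                               transition_count_table)
from conftest import toy_panel


def model_with_rates(rates, **kw) -> TransitionModel:
    tm = TransitionModel(**kw)
    tm.theta = {tr: np.log(rates[tr]) for tr in tm.transitions}
    return tm


class TestTransitionCountTable:
    def test_hand_enumerated_pairs(self):
        panel = pd.DataFrame({
            "child_id": [1, 1, 2, 2, 3, 3],
            "time_months": [0, 18, 0, 18, 0, 18],
            "state": [1, 2, 1, 1, 2, 3],
        })
        table = transition_count_table(panel)
        assert list(table.counts.loc[1, [1, 2, 3]]) == [1, 1, 0]
        assert list(table.counts.loc[2, [1, 2, 3]]) == [0, 0, 1]
        assert table.counts.loc[1, "total"] == 2
        assert table.pct.loc[1, 2] == 50.0

    def test_empty_panel(self):
        table = transition_count_table(pd.DataFrame(
            columns=["child_id", "time_months", "state"]))
        assert table.n_pairs == 0
        assert (table.counts[[1, 2, 3]].to_numpy() == 0).all()

    def test_pair_count_conservation(self, small_cohort):
        panel, _ = small_cohort
        table = transition_count_table(panel)
        expected = (panel.groupby("child_id").size() - 1).sum()
        assert table.n_pairs == expected


class TestApplyCovariates:
    def test_zero_betas_reproduce_baseline(self, baseline_rates):
        tm = model_with_rates(baseline_rates, covariates=("sex",))
        tm.beta = {tr: {"sex": 0.0} for tr in tm.transitions}
        q = apply_covariates(tm, {"sex": 1.0})
        assert np.allclose(q.matrix, build_intensity_matrix(baseline_rates).matrix)

    def test_hazard_ratio_multiplies_rate(self, baseline_rates):
        tm = model_with_rates(baseline_rates, covariates=("sex",),
                              covariate_map={(2, 1): ("sex",)})
        tm.beta = {(2, 1): {"sex": np.log(0.8013)}}
        q = apply_covariates(tm, {"sex": 1.0})
        assert q.matrix[1, 0] == pytest.approx(0.8013 * baseline_rates[(2, 1)])

    def test_log_linearity(self, baseline_rates):
        tm = model_with_rates(baseline_rates, covariates=("x",))
        tm.beta = {tr: {"x": 0.3} for tr in tm.transitions}
        q1 = apply_covariates(tm, {"x": 1.0})
        q2 = apply_covariates(tm, {"x": 2.0})
        ratio = np.log(q2.matrix[0, 1] / baseline_rates[(1, 2)])
        assert ratio == pytest.approx(2 * np.log(q1.matrix[0, 1] / baseline_rates[(1, 2)]))

    def test_missing_covariate_rejected(self, baseline_rates):
        tm = model_with_rates(baseline_rates, covariates=("sex",))
        with pytest.raises(ValueError):
            apply_covariates(tm, None)


class TestPanelLoglikelihood:
    def test_frozen_chain_same_state_is_zero(self):
        panel = pd.DataFrame({"child_id": [1, 1], "time_months": [0.0, 18.0],
                              "state": [2, 2]})
        tm = TransitionModel(mask=np.zeros((3, 3), bool))  # Q = 0
        assert panel_loglikelihood(tm, panel) == 0.0

    def test_single_pair_matches_expm_entry(self, baseline_rates):
        panel = pd.DataFrame({"child_id": [1, 1], "time_months": [0.0, 18.0],
                              "state": [1, 2]})
        tm = model_with_rates(baseline_rates)
        q = build_intensity_matrix(baseline_rates).matrix
        expected = np.log(expm(18.0 * q)[0, 1])
        assert panel_loglikelihood(tm, panel) == pytest.approx(expected, abs=1e-12)

    def test_additive_over_children(self, baseline_rates):
        tm = model_with_rates(baseline_rates)
        panel = toy_panel()
        total = panel_loglikelihood(tm, panel)
        parts = sum(
            panel_loglikelihood(tm, panel[panel["child_id"] == c])
            for c in (1, 2, 3)
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_impossible_transition_is_minus_inf(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 1] = True  # only 1 -> 2 allowed; 2 -> 1 unreachable
        tm = TransitionModel(mask=mask)
        tm.theta = {(1, 2): np.log(0.01)}
        panel = pd.DataFrame({"child_id": [1, 1], "time_months": [0.0, 18.0],
                              "state": [2, 1]})
        with pytest.warns(UserWarning, match="impossible"):
            assert panel_loglikelihood(tm, panel) == -np.inf


class TestPreparePanel:
    def test_drops_single_observation_children(self):
        panel = pd.DataFrame({"child_id": [1, 1, 2], "time_months": [0, 18, 0],
                              "state": [1, 2, 3]})
        with pytest.warns(UserWarning, match="dropped 1 children"):
            out = prepare_panel(panel)
        assert set(out["child_id"]) == {1}

    def test_rejects_bad_states(self):
        panel = pd.DataFrame({"child_id": [1, 1], "time_months": [0, 18],
                              "state": [1, 4]})
        with pytest.raises(ValueError, match="states outside"):
            prepare_panel(panel)

    def test_rejects_non_increasing_times(self):
        panel = pd.DataFrame({"child_id": [1, 1], "time_months": [18, 18],
                              "state": [1, 2]})
        with pytest.raises(ValueError, match="strictly increasing"):
            prepare_panel(panel)


class TestFit:
    def test_aic_identity(self, small_fit):
        assert small_fit.aic_ == pytest.approx(small_fit.minus2ll_ + 2 * small_fit.df_)
        assert small_fit.df_ == 6

    def test_children_order_invariance(self, small_cohort):
        panel, _ = small_cohort
        est1 = MultiStateMarkovModel()
        est2 = MultiStateMarkovModel()
        shuffled = pd.concat(
            [panel[panel["child_id"] == c]
             for c in np.random.default_rng(3).permutation(panel["child_id"].unique())],
            ignore_index=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est1.fit(panel)
            est2.fit(shuffled)
        assert np.allclose(est1.params_, est2.params_, atol=1e-8)

    def test_error_shrinks_with_sample_size(self, baseline_rates):
        """Median absolute estimation error decreases as the cohort grows."""
        truth = build_intensity_matrix(baseline_rates).matrix
        mae = []
        for n in (300, 1000, 3000):
            errs = []
            for rep in range(3):
                panel, _ = generate_cohort(CohortConfig(n_children=n, seed=50 + rep))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = MultiStateMarkovModel().fit(panel)
                q = est.intensity_matrix().matrix
                off = ~np.eye(3, dtype=bool)
                errs.append(np.abs((q - truth))[off].mean())
            mae.append(np.median(errs))
        assert mae[0] > mae[1] > mae[2]

    def test_estimates_within_wald_band_of_truth(self, small_fit, baseline_rates):
        """On its own data the fit stays within ~4 SE of the generating rates."""
        tab = small_fit.intensity_table()
        for _, row in tab.iterrows():
            q = baseline_rates[(int(row["from"]), int(row["to"]))]
            se_log = np.log(row["upper"] / row["estimate"]) / 1.96
            assert abs(np.log(row["estimate"] / q)) < 4.5 * se_log

    def test_wrong_mask_has_higher_aic(self):
        """Dropping transitions the data uses costs more likelihood than 2 df."""
        panel, _ = generate_cohort(CohortConfig(n_children=1500, seed=21))
        bad_mask = ~np.eye(3, dtype=bool)
        bad_mask[0, 2] = bad_mask[2, 0] = False  # forbid direct 1<->3 moves
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            good = MultiStateMarkovModel().fit(panel)
            bad = MultiStateMarkovModel(mask=bad_mask).fit(panel)
        assert good.aic_ < bad.aic_

    def test_unfitted_access_raises(self):
        with pytest.raises(AttributeError):
            MultiStateMarkovModel().intensity_matrix()

    def test_sklearn_param_protocol(self):
        est = MultiStateMarkovModel(covariates=("sex",))
        params = est.get_params()
        clone = MultiStateMarkovModel().set_params(**params)
        assert clone.get_params() == params

    def test_fit_msm_wrapper_matches_estimator(self, small_cohort, small_fit):
        panel, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = fit_msm(panel)
        assert np.allclose(est.params_, small_fit.params_, atol=1e-8)

    def test_to_json_stable(self, small_fit):
        import json
        obj = json.loads(small_fit.to_json())
        assert list(obj) == sorted(obj)
        assert obj["df"] == 6


class TestHazardRatios:
    def test_reference_model_has_unit_hr(self, small_cohort):
        """Fitting a pure-noise covariate gives HRs near 1 with CIs crossing 1."""
        panel, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = MultiStateMarkovModel(
                covariates=("sex",), covariate_map={(2, 1): ("sex",)}).fit(panel)
        hr = est.hazard_ratio_table()
        assert len(hr) == 1
        row = hr.iloc[0]
        assert (row["from"], row["to"], row["covariate"]) == (2, 1, "sex")
        assert row["lower"] < 1.0 < row["upper"]

    def test_reported_transitions_exposed(self, small_cohort):
        panel, _ = small_cohort
        cmap = {tr: ("sex",) for tr in [(2, 1), (1, 2), (2, 3), (3, 2)]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = MultiStateMarkovModel(covariates=("sex",), covariate_map=cmap).fit(panel)
        hr = est.hazard_ratio_table()
        assert set(zip(hr["from"], hr["to"])) == set(cmap)
        assert est.df_ == 6 + 4


class TestBootstrap:
    def test_smoke_two_replicates(self, small_fit, small_cohort):
        panel, _ = small_cohort
        out = bootstrap_derived(small_fit, panel, "sojourn", B=2, seed=1)
        reps = out["replicates"]
        assert reps.shape[0] == 2
        assert np.all(out["lower"] >= reps.min(axis=0) - 1e-12)
        assert np.all(out["upper"] <= reps.max(axis=0) + 1e-12)

    def test_deterministic_under_seed(self, small_fit, small_cohort):
        panel, _ = small_cohort
        a = bootstrap_derived(small_fit, panel, "next_state", B=3, seed=9)
        b = bootstrap_derived(small_fit, panel, "next_state", B=3, seed=9)
        assert np.array_equal(a["lower"], b["lower"], equal_nan=True)
        assert np.array_equal(a["upper"], b["upper"], equal_nan=True)

    def test_point_inside_own_interval(self, small_fit, small_cohort):
        panel, _ = small_cohort
        out = bootstrap_derived(small_fit, panel, "sojourn", B=60, seed=4)
        assert np.all(out["point"] >= out["lower"] - 1e-9)
        assert np.all(out["point"] <= out["upper"] + 1e-9)

    def test_invalid_b_rejected(self, small_fit, small_cohort):
        panel, _ = small_cohort
        with pytest.raises(ValueError):
            bootstrap_derived(small_fit, panel, "sojourn", B=1)


def test_delta_se_agrees_with_parametric_bootstrap(baseline_rates):
    """Delta-method SE of log q21 vs the sd over parametric refits (within 20%)."""
    panel, _ = generate_cohort(CohortConfig(n_children=600, seed=31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MultiStateMarkovModel().fit(panel)
    k = fit.transitions_.index((2, 1))
    delta_se = np.sqrt(fit.covariance_[k, k])
    rates = {tr: np.exp(fit.theta_[tr]) for tr in fit.transitions_}
    reps = []
    for b in range(100):
        cfg = CohortConfig(n_children=600, seed=7000 + b, true_Q0=rates)
        sim_panel, _ = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = MultiStateMarkovModel().fit(sim_panel, init_params=fit.params_)
        reps.append(refit.params_[k])
    boot_sd = np.std(reps, ddof=1)
    assert abs(delta_se / boot_sd - 1.0) < 0.2
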