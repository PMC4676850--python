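"""Cross-validation mechanics, the trial-correct metric, chance level,
diagnostics and IMI scoring."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from gaitintent import evaluation as ev
from gaitintent.core_io import IMI_REVERSE_ITEMS, IMI_SUBSCALES, PipelineConfig
from gaitintent.detector import SLDAModel


class TestChronologicalFolds:
    def test_ten_trials_five_folds(self):
        folds = ev.chronological_folds(10, 5)
        tests = [list(te) for _, te in folds]
        assert tests == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]

    def test_folds_partition_all_trials(self):
        folds = ev.chronological_folds(23, 4)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(23))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)
            assert np.all(np.diff(te) == 1)  # contiguous blocks

    def test_96_trials_split_20_19_19_19_19(self):
        sizes = sorted((len(te) for _, te in ev.chronological_folds(96, 5)),
                       reverse=True)
        assert sizes == [20, 19, 19, 19, 19]

    def test_more_folds_than_trials_rejected(self):
        with pytest.raises(ev.ContractError):
            ev.chronological_folds(3, 5)


class TestTrialCorrect:
    def test_perfect_prediction_is_correct(self):
        labels = np.array([0, 0, 0, 1, 1])
        assert ev.trial_correct(labels, labels)

    def test_all_zeros_fails_sensitivity(self):
        labels = np.array([0, 0, 1, 1])
        assert not ev.trial_correct(np.zeros(4, dtype=int), labels)

    def test_one_rest_positive_fails_specificity(self):
        labels = np.array([0, 0, 0, 1, 1])
        pred = np.array([1, 0, 0, 1, 1])
        assert not ev.trial_correct(pred, labels)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ev.ContractError):
            ev.trial_correct([0, 1], [0, 1, 1])

    def test_matches_brute_force_on_random_sequences(self, rng):
        def brute(pred, labels):
            tp = fp = 0
            for p, l in zip(pred, labels):
                if p == 1 and l == 1:
                    tp += 1
                if p == 1 and l == 0:
                    fp += 1
            return tp >= 1 and fp == 0

        for _ in range(10_000):
            n = rng.integers(2, 30)
            labels = (np.arange(n) >= rng.integers(1, n)).astype(int)
            pred = rng.integers(0, 2, n)
            assert ev.trial_correct(pred, labels) == brute(pred, labels)


class TestChanceLevel:
    def test_matches_analytic_value_within_3_se(self):
        params = ev.ChanceParams()
        p = ev.chance_level_analytic(params) / 100.0
        se = 100.0 * np.sqrt(p * (1 - p) / params.n_draws)
        mc = ev.chance_level(params, seed=0)
        assert abs(mc - ev.chance_level_analytic(params)) <= 3 * se

    @pytest.mark.parametrize("n_windows,n_pre", [(41, 8), (20, 5), (10, 3),
                                                 (50, 25), (7, 6)])
    def test_analytic_value_is_one_over_positions(self, n_windows, n_pre):
        params = ev.ChanceParams(n_windows=n_windows, n_pre=n_pre,
                                 n_draws=200_000)
        expected = 100.0 / (n_windows - n_pre + 1)
        assert ev.chance_level_analytic(params) == pytest.approx(expected)
        assert ev.chance_level(params, seed=3) == pytest.approx(expected,
                                                                abs=0.5)

    def test_full_length_block_is_always_correct(self):
        params = ev.ChanceParams(n_windows=8, n_pre=8, n_draws=1000)
        assert ev.chance_level(params, seed=0) == 100.0
        params = ev.ChanceParams(n_windows=8, n_pre=7, n_draws=2000)
        # two positions; only flush-right counts, so ~50 %
        assert ev.chance_level(params, seed=0) == pytest.approx(50.0, abs=5.0)

    def test_monte_carlo_error_shrinks_with_draws(self):
        params_small = ev.ChanceParams(n_draws=1000)
        params_big = ev.ChanceParams(n_draws=100_000)
        target = ev.chance_level_analytic(params_small)
        err_small = [abs(ev.chance_level(params_small, seed=s) - target)
                     for s in range(10)]
        err_big = [abs(ev.chance_level(params_big, seed=s) - target)
                   for s in range(10)]
        assert np.mean(err_big) < np.mean(err_small)


@pytest.fixture(scope="module")
def small_cv_setup():
    """A 30-trial session and reduced config for fast nested-CV runs."""
    from gaitintent import emg_onset, synthetic_data as sd
    from gaitintent.detector import HyperGrid

    protocol = sd.ProtocolParams(n_phases=3, trials_per_phase=10,
                                 relax_duration_s=9.0, relax_jitter_s=0.5)
    rec, truth = sd.generate_session(protocol, seed=33)
    trials = emg_onset.epoch_trials(rec, emg_onset.compute_onsets(rec))
    cfg = PipelineConfig(seed=0)
    cfg.grid = HyperGrid(l1=(0.0, 0.01), l2=(0.01,),
                         threshold=(0.3, 0.6, 0.9))
    return trials, cfg


class TestNestedCV:
    def test_every_kept_trial_tested_exactly_once(self, small_cv_setup):
        trials, cfg = small_cv_setup
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ev.run_nested_cv(trials, cfg)
        kept = [t for t in trials if t.kept]
        tested = [i for f in res.folds for i in f.test_indices]
        assert sorted(tested) == list(range(len(kept)))
        for f in res.folds:
            assert 0.0 <= f.percent_correct <= 100.0

    def test_corrupting_test_trials_leaves_trained_models_unchanged(
            self, small_cv_setup):
        """Train/test isolation: test-fold data cannot leak into training."""
        trials, cfg = small_cv_setup
        kept = [t for t in trials if t.kept]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_a = ev.run_nested_cv(kept, cfg)
            corrupted = [t for t in kept]
            # scale every trial of the LAST test fold only
            last_fold = res_a.folds[-1].test_indices
            for i in last_fold:
                t = corrupted[i]
                import dataclasses

                corrupted[i] = dataclasses.replace(t, eeg=t.eeg * 3.0)
            res_b = ev.run_nested_cv(corrupted, cfg)
        assert np.array_equal(res_a.folds[-1].mrcp_weights,
                              res_b.folds[-1].mrcp_weights)
        assert np.array_equal(res_a.folds[-1].erd_weights,
                              res_b.folds[-1].erd_weights)

    def test_self_transfer_is_at_least_as_good_as_cross_validation(
            self, small_cv_setup):
        trials, cfg = small_cv_setup
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = ev.run_nested_cv(trials, cfg).percent_correct
            self_tr = ev.session_transfer(trials, trials, cfg)
        assert self_tr >= cv - 1e-9

    def test_too_few_trials_rejected(self, small_cv_setup):
        trials, cfg = small_cv_setup
        with pytest.raises(ev.ContractError):
            ev.run_nested_cv(trials[:10], cfg)


class TestDiagnostics:
    def test_r2_of_label_equal_feature_is_one(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        assert ev.r2_pointbiserial(labels.astype(float), labels) == pytest.approx(1.0)

    def test_r2_of_independent_feature_is_near_zero(self, rng):
        labels = rng.integers(0, 2, 10_000)
        x = rng.standard_normal(10_000)
        assert ev.r2_pointbiserial(x, labels) < 0.01

    def test_r2_toy_example(self):
        # {(0,0),(1,0),(2,1),(3,1)}: r = 2/sqrt(5), r^2 = 0.8
        assert ev.r2_pointbiserial(np.array([0.0, 1, 2, 3]),
                                   np.array([0, 0, 1, 1])) == pytest.approx(0.8)

    def test_constant_feature_r2_is_zero(self):
        assert ev.r2_pointbiserial(np.ones(6), np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_feature_consistency_percentages(self):
        def model(w):
            return SLDAModel(np.array(w), np.zeros(3), 0.0, 0.0)

        models = [model([1.0, 0.0, 2.0])] * 5 + [model([1.0, 0.0, 0.0])]
        cons = ev.feature_consistency(models)
        assert cons[0] == 100.0
        assert cons[1] == 0.0
        assert cons[2] == pytest.approx(100 * 5 / 6)

    def test_weight_ratio_trivial_cases(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from gaitintent.detector import EnsembleModel

        lda = LinearDiscriminantAnalysis()
        lda.fit(np.array([[0.1, 0.1], [0.9, 0.9], [0.2, 0.3], [0.8, 0.7]]),
                np.array([0, 1, 0, 1]))

        def ens(w_m, w_e):
            return EnsembleModel(
                SLDAModel(np.array(w_m), np.zeros(len(w_m)), 0, 0),
                SLDAModel(np.array(w_e), np.zeros(len(w_e)), 0, 0),
                lda, 0.5)

        assert ev.weight_ratio([ens([1.0, 1.0], [0.0])]) == 0.0
        assert ev.weight_ratio([ens([1.0, 2.0], [3.0])]) == pytest.approx(1.0)
        assert np.isnan(ev.weight_ratio([ens([0.0], [1.0])]))


class TestImi:
    def _table(self, fill=7, overrides=None):
        row = {f"item_{i}": fill for i in range(1, 38)}
        for k, v in (overrides or {}).items():
            row[f"item_{k}"] = v
        return pd.DataFrame([{"subject": "S01", "session": 1, **row}])

    def test_ceiling_scores_without_reverse_items(self):
        scores = ev.imi_scores(self._table(7))
        for name, items in IMI_SUBSCALES.items():
            if not set(items) & set(IMI_REVERSE_ITEMS):
                assert scores[name].iloc[0] == 7.0

    def test_reverse_item_scored_2_contributes_6(self):
        base = ev.imi_scores(self._table(4))
        rev = IMI_REVERSE_ITEMS[0]
        subscale = next(n for n, its in IMI_SUBSCALES.items() if rev in its)
        bumped = ev.imi_scores(self._table(4, {rev: 2}))
        k = len(IMI_SUBSCALES[subscale])
        assert bumped[subscale].iloc[0] - base[subscale].iloc[0] == \
            pytest.approx((6 - 4) / k)

    def test_uniform_random_items_average_to_midscale(self, rng):
        rows = []
        for s in range(300):
            rows.append({"subject": f"S{s}", "session": 1,
                         **{f"item_{i}": int(rng.integers(1, 8))
                            for i in range(1, 38)}})
        scores = ev.imi_scores(pd.DataFrame(rows))
        for name in IMI_SUBSCALES:
            assert scores[name].mean() == pytest.approx(4.0, abs=0.15)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ev.DataError):
            ev.imi_scores(self._table(7, {1: 9}))


class TestCorrelatePerformance:
    def test_perfectly_linear_pairs_give_r_one(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({name: rng.standard_normal(10)
                               for name in IMI_SUBSCALES})
        perf = 2.0 * scores["interest_enjoyment"].to_numpy() + 1.0
        out = ev.correlate_performance(perf, scores)
        row = out[out.subscale == "interest_enjoyment"].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_adjusted == out.p_adjusted.min()

    def test_holm_step_down_oracle_values(self):
        # statsmodels is the oracle: (0.01, 0.02, 0.9 x4) ->
        # (0.06, 0.10, 1.0, 1.0, 1.0, 1.0)
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.01, 0.02, 0.9, 0.9, 0.9, 0.9])
        adj = multipletests(raw, method="holm")[1]
        assert np.allclose(adj, [0.06, 0.10, 1.0, 1.0, 1.0, 1.0])

    def test_holm_adjustment_is_monotone_and_not_below_raw(self, rng):
        scores = pd.DataFrame({name: rng.standard_normal(15)
                               for name in IMI_SUBSCALES})
        perf = rng.standard_normal(15)
        out = ev.correlate_performance(perf, scores)
        assert np.all(out.p_adjusted >= out.p_raw - 1e-12)
        s = out.sort_values("p_raw")
        assert np.all(np.diff(s.p_adjusted) >= -1e-12)

    def test_zero_variance_subscale_reported_as_nan(self, rng):
        scores = pd.DataFrame({name: rng.standard_normal(8)
                               for name in IMI_SUBSCALES})
        scores["pressure_tension"] = 3.0
        out = ev.correlate_performance(rng.standard_normal(8), scores)
        assert np.isnan(out[out.subscale == "pressure_tension"].r.iloc[0])

    def test_fewer_than_three_pairs_rejected(self):
        scores = pd.DataFrame({name: [1.0, 2.0] for name in IMI_SUBSCALES})
        with pytest.raises(ev.ContractError):
            ev.correlate_performance([1.0, 2.0], scores)
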