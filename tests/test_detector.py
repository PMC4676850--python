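"""Sparse discriminant first layer, probability calibration, and the
two-layer ensemble."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gaitintent import detector as dt
from gaitintent.features import WindowSequence


def gaussian_toy(rng, n=50, p=5, effect=None):
    effect = np.array([1.0, 0.5, 0.0, 0.0, -0.3]) if effect is None else effect
    scale = np.diag([1.0, 2.0, 1.0, 0.5, 1.0])[:p, :p]
    X0 = rng.standard_normal((n, p)) @ scale
    X1 = rng.standard_normal((n, p)) @ scale + effect[:p]
    return np.vstack([X0, X1]), np.repeat([0, 1], n)


def make_sequences(rng, n_trials=12, n_windows=41, n_pre=8, effect=3.0,
                   n_mrcp=20, n_erd=5):
    """Separable synthetic window sequences (signal in both feature sets)."""
    seqs = []
    starts = -6.0 + 0.125 * np.arange(n_windows)
    labels = np.zeros(n_windows, dtype=int)
    labels[-n_pre:] = 1
    for k in range(n_trials):
        Xm = rng.standard_normal((n_windows, n_mrcp))
        Xe = rng.standard_normal((n_windows, n_erd))
        Xm[labels == 1, 0] += effect
        Xe[labels == 1, 0] -= effect
        seqs.append(WindowSequence(starts, starts + 1.0, labels.copy(),
                                   Xm, Xe, trial_index=k))
    return seqs


class TestFitSlda:
    def test_l1_zero_matches_ridge_lda_direction(self, rng):
        X, y = gaussian_toy(rng)
        l2 = 0.1
        m = dt.fit_slda(X, y, 0.0, l2)
        Xc = X - X.mean(axis=0)
        Sigma = Xc.T @ Xc / len(y)
        mu_d = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        oracle = np.linalg.solve(Sigma + l2 * np.eye(X.shape[1]), mu_d)
        cos = m.weights @ oracle / (np.linalg.norm(m.weights)
                                    * np.linalg.norm(oracle))
        assert cos > 0.999

    def test_informative_dimension_dominates_under_l1(self, rng):
        n, p = 200, 21
        X = rng.standard_normal((n, p))
        y = np.repeat([0, 1], n // 2)
        X[:, 0] += 3.0 * y
        m = dt.fit_slda(X, y, l1=0.05, l2=0.01)
        assert np.argmax(np.abs(m.weights)) == 0
        assert (m.weights[1:] == 0).mean() >= 0.5

    def test_duplicating_training_points_changes_nothing(self, rng):
        X, y = gaussian_toy(rng, n=30)
        a = dt.fit_slda(X, y, 0.01, 0.01)
        b = dt.fit_slda(np.vstack([X, X]), np.concatenate([y, y]), 0.01, 0.01)
        assert np.allclose(a.weights, b.weights, atol=1e-8)

    def test_single_class_is_a_contract_error(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(dt.ContractError):
            dt.fit_slda(X, np.zeros(20, dtype=int), 0.0, 0.1)

    def test_crushing_penalty_keeps_one_guard_weight(self, rng):
        X, y = gaussian_toy(rng)
        with pytest.warns(UserWarning, match="vanished"):
            m = dt.fit_slda(X, y, l1=1e6, l2=0.1)
        assert m.n_nonzero == 1

    def test_sparsity_monotone_in_l1_on_average(self):
        l1_grid = [0.0, 0.01, 0.05, 0.2, 1.0]
        counts = np.zeros(len(l1_grid))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = gaussian_toy(rng, n=60, p=5)
            for i, l1 in enumerate(l1_grid):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    counts[i] += dt.fit_slda(X, y, l1, 0.01).n_nonzero
        assert np.all(np.diff(counts) <= 0)


class TestProbability:
    def test_midpoint_of_balanced_classes_is_half(self, rng):
        X, y = gaussian_toy(rng)
        m = dt.fit_slda(X, y, 0.0, 0.01)
        mid_proj = 0.5 * (m.proj_mean_rest + m.proj_mean_pre)
        # invert the projection at the midpoint via the stored mean
        x = m.feature_mean + mid_proj * m.weights / (m.weights @ m.weights)
        assert dt.slda_proba(m, x[None])[0] == pytest.approx(0.5, abs=1e-9)

    def test_saturates_to_one_far_on_the_positive_side(self, rng):
        X, y = gaussian_toy(rng)
        m = dt.fit_slda(X, y, 0.0, 0.01)
        x = m.feature_mean + 1e4 * m.weights / np.linalg.norm(m.weights) ** 2 \
            * (m.proj_mean_pre - m.proj_mean_rest)
        assert dt.slda_proba(m, x[None])[0] > 1 - 1e-6

    def test_monotone_along_the_discriminant(self, rng):
        X, y = gaussian_toy(rng)
        m = dt.fit_slda(X, y, 0.0, 0.01)
        ts = np.linspace(-5, 5, 41)
        pts = m.feature_mean + np.outer(ts, m.weights)
        probs = dt.slda_proba(m, pts)
        assert np.all(np.diff(probs) >= 0)


class TestEnsemble:
    def test_separable_features_reach_perfect_inner_score(self, rng, reduced_grid):
        seqs = make_sequences(rng, n_trials=15, effect=4.0)
        model = dt.fit_ensemble(seqs, reduced_grid, inner_folds=3)
        assert model.inner_score == pytest.approx(100.0)
        out = dt.detect(model, seqs[0])
        assert out[seqs[0].labels == 1].any()
        assert not out[seqs[0].labels == 0].any()

    def test_single_point_grid_is_selected(self, rng):
        grid = dt.HyperGrid(l1=(0.01,), l2=(0.1,), threshold=(0.5,))
        seqs = make_sequences(rng, n_trials=8)
        model = dt.fit_ensemble(seqs, grid, inner_folds=2)
        assert model.mrcp_model.l1 == 0.01 and model.mrcp_model.l2 == 0.1
        assert model.probability_threshold == 0.5

    def test_randomized_labels_stay_near_chance(self, rng, reduced_grid):
        seqs = make_sequences(rng, n_trials=20, effect=0.0)
        model = dt.fit_ensemble(seqs, reduced_grid, inner_folds=4)
        from gaitintent.evaluation import trial_correct

        flags = [trial_correct(dt.detect(model, s), s.labels) for s in seqs]
        # training-set resubstitution on pure noise still hovers near chance
        assert 100.0 * np.mean(flags) <= 25.0

    def test_threshold_edges_detect_all_or_nothing(self, rng, reduced_grid):
        seqs = make_sequences(rng, n_trials=8)
        model = dt.fit_ensemble(seqs, reduced_grid, inner_folds=2)
        model.probability_threshold = 1.0
        assert not dt.detect(model, seqs[0]).any()
        model.probability_threshold = 0.0
        assert dt.detect(model, seqs[0]).all()

    def test_uninformative_layer_degrades_gracefully(self, rng, reduced_grid):
        """With one noise-only feature set the ensemble stays within 5 points
        of the informative layer alone."""
        from gaitintent.evaluation import trial_correct

        perf = lambda m, seqs: 100.0 * np.mean(
            [trial_correct(dt.detect(m, s), s.labels) for s in seqs])
        alone_scores, one_scores = [], []
        for seed in range(3):
            seed_rng = np.random.default_rng(seed)
            base = make_sequences(seed_rng, n_trials=50, effect=4.0)
            # dead ERD layer: pure noise features
            seqs_one = [WindowSequence(s.starts, s.ends, s.labels, s.mrcp,
                                       seed_rng.standard_normal(s.erd.shape),
                                       s.trial_index)
                        for s in base]
            # informative layer alone: both slots see the MRCP features
            seqs_alone = [WindowSequence(s.starts, s.ends, s.labels, s.mrcp,
                                         s.mrcp, s.trial_index) for s in base]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m_a = dt.fit_ensemble(seqs_alone[:25], reduced_grid, inner_folds=3)
                m_o = dt.fit_ensemble(seqs_one[:25], reduced_grid, inner_folds=3)
            alone_scores.append(perf(m_a, seqs_alone[25:]))
            one_scores.append(perf(m_o, seqs_one[25:]))
        assert np.mean(one_scores) >= np.mean(alone_scores) - 5.0

    def test_model_json_round_trip(self, rng, reduced_grid, tmp_path):
        import json

        seqs = make_sequences(rng, n_trials=8)
        model = dt.fit_ensemble(seqs, reduced_grid, inner_folds=2)
        model.to_json(tmp_path / "m.json")
        d = json.loads((tmp_path / "m.json").read_text())
        assert len(d["mrcp_weights"]) == seqs[0].mrcp.shape[1]
        assert d["threshold"] == model.probability_threshold
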