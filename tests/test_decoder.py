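"""SVM decoding: cross-validation, feature selection, Platt calibration."""

import numpy as np
import pytest
from scipy.optimize import minimize

import ssvepbci as sb
from ssvepbci.containers import ATTEND_FACE, ATTEND_GABOR
from ssvepbci.decoder import NotCalibratedError, _folds, platt_probability

from conftest import compact_config, simulate_baseline


def two_gaussians(rng, n_per_class=30, n_features=4, sep=6.0):
    """Well-separated synthetic features with attend-Gabor as class 1."""
    x0 = rng.standard_normal((n_per_class, n_features))
    x1 = rng.standard_normal((n_per_class, n_features)) + sep
    X = np.vstack([x0, x1])
    labels = [ATTEND_FACE] * n_per_class + [ATTEND_GABOR] * n_per_class
    return X, labels


class TestCrossValidate:
    def test_separable_data_is_perfect(self, rng):
        X, labels = two_gaussians(rng)
        # separability confirmed by a nearest-centroid oracle
        c0, c1 = X[:30].mean(axis=0), X[30:].mean(axis=0)
        d0 = np.linalg.norm(X - c0, axis=1)
        d1 = np.linalg.norm(X - c1, axis=1)
        oracle = np.mean((d1 < d0) == (np.arange(60) >= 30))
        assert oracle == 1.0
        mean, sd = sb.cross_validate(X, "linear", seed=0, labels=labels)
        assert mean == 1.0 and sd == 0.0

    def test_permuted_labels_are_chance(self, rng):
        """Random labels on 200 trials: mean accuracy 0.5 +/- 0.1 over 20 seeds."""
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 6))
            labels = r.permutation([ATTEND_GABOR] * 100 + [ATTEND_FACE] * 100)
            accs.append(sb.cross_validate(X, "linear", seed=seed, labels=list(labels))[0])
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_leave_one_out_fold_count(self):
        y = np.array([0, 1] * 10)
        folds = _folds(y, k=len(y), seed=0)
        assert len(folds) == len(y)
        assert all(len(test) == 1 for _, test in folds)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            sb.cross_validate(X, "linear", labels=[ATTEND_GABOR] * 20)

    def test_deterministic_given_seed(self, rng):
        X, labels = two_gaussians(rng, sep=1.0)
        a = sb.cross_validate(X, "rbf", seed=3, labels=labels)
        b = sb.cross_validate(X, "rbf", seed=3, labels=labels)
        assert a == b


class TestForwardFeatureSelection:
    def test_informative_features_recovered(self, rng):
        """2 informative + 20 noise columns: both informative ones selected."""
        y_bits = np.array([0] * 30 + [1] * 30)
        # jointly separable pair: a shared nuisance component cancels only
        # when both features are in the model
        shared = 2.0 * rng.standard_normal(60)
        f0 = 3.0 * y_bits + shared + 0.2 * rng.standard_normal(60)
        f1 = shared + 0.2 * rng.standard_normal(60)
        noise = rng.standard_normal((60, 20))
        X = np.column_stack([f0, f1, noise])
        labels = [ATTEND_GABOR if b else ATTEND_FACE for b in y_bits]
        cols = sb.forward_feature_selection(X, "linear", seed=1, labels=labels)
        assert {0, 1}.issubset(cols)
        acc_sel = sb.cross_validate(X[:, cols], "linear", seed=1, labels=labels)[0]
        acc_inf = sb.cross_validate(X[:, :2], "linear", seed=1, labels=labels)[0]
        assert acc_sel >= acc_inf - 0.05

    def test_single_feature_matrix(self, rng):
        X = rng.standard_normal((20, 1))
        labels = [ATTEND_GABOR, ATTEND_FACE] * 10
        assert sb.forward_feature_selection(X, "linear", labels=labels) == [0]

    def test_subset_no_worse_than_full_set_on_same_folds(self, rng):
        y_bits = np.array([0] * 30 + [1] * 30)
        X = np.column_stack([
            y_bits * 2.0 + rng.standard_normal(60),
            rng.standard_normal((60, 10)),
        ])
        labels = [ATTEND_GABOR if b else ATTEND_FACE for b in y_bits]
        y = np.array(y_bits)
        folds = _folds(y, 5, 1)
        from ssvepbci.decoder import _fold_accuracies

        cols = sb.forward_feature_selection(X, "linear", seed=1, labels=labels)
        acc_sel = np.mean(_fold_accuracies(X[:, cols], y, "linear", folds))
        acc_full = np.mean(_fold_accuracies(X, y, "linear", folds))
        assert 1 - acc_sel <= 1 - acc_full + 1e-12


class TestPlatt:
    def test_separated_decision_values(self):
        # Platt's target shifts cap probabilities at (N+1)/(N+2); with 20
        # examples per class the cap is 0.954, leaving room above 0.9
        s = np.concatenate([np.linspace(-2.7, -2.3, 20), np.linspace(2.3, 2.7, 20)])
        y = np.repeat([0, 1], 20)
        A, B = sb.fit_platt(s, y)
        p = platt_probability(s, (A, B))
        assert np.all(p[y == 1] > 0.9) and np.all(p[y == 0] < 0.1)
        assert A < 0  # P increasing in s

    def test_matches_independent_optimizer(self, rng):
        """Newton solution equals a Nelder-Mead fit of the same likelihood."""
        s = rng.standard_normal(80) + np.repeat([0.8, -0.8], 40)
        y = np.repeat([1, 0], 40)
        A, B = sb.fit_platt(s, y)

        n_pos, n_neg = 40, 40
        t = np.where(y == 1, (n_pos + 1) / (n_pos + 2), 1 / (n_neg + 2))

        def nll(ab):
            f = ab[0] * s + ab[1]
            return np.sum(np.where(f >= 0, t * f + np.log1p(np.exp(-f)),
                                   (t - 1) * f + np.log1p(np.exp(f))))

        ref = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        np.testing.assert_allclose(
            platt_probability(s, (A, B)), platt_probability(s, tuple(ref.x)), atol=1e-6
        )

    def test_monotone_in_decision_value(self, rng):
        s = rng.standard_normal(40)
        y = (s + 0.3 * rng.standard_normal(40) > 0).astype(int)
        ab = sb.fit_platt(s, y)
        grid = np.linspace(-5, 5, 101)
        p = platt_probability(grid, ab)
        assert np.all(np.diff(p) >= 0) or np.all(np.diff(p) <= 0)

    def test_symmetric_values_give_half_at_zero(self):
        s = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        ab = sb.fit_platt(s, y)
        assert platt_probability(0.0, ab) == pytest.approx(0.5, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sb.fit_platt([1.0, 2.0], [1, 1])


class TestAttentionDecoder:
    def test_split_arithmetic(self, fitted_decoder):
        assert fitted_decoder.n_train == 48
        assert fitted_decoder.n_validation == 12

    def test_high_contrast_validation_accuracy(self, fitted_decoder):
        assert fitted_decoder.validation_accuracy >= 0.9

    def test_same_seed_identical_probabilities(self, baseline_epochs):
        probe = sb.simulate_epoch(compact_config(), ATTEND_GABOR, seed=999)
        p = []
        for _ in range(2):
            res = sb.AttentionDecoder(baseline_epochs).fit(seed=4)
            p.append(res.gabor_probability(probe).probability)
        assert p[0] == p[1]

    def test_unbalanced_input_rejected(self, baseline_epochs):
        with pytest.raises(ValueError, match="balanced"):
            sb.AttentionDecoder(baseline_epochs[:40])  # 30 gabor + 10 face

    def test_too_small_input_rejected(self, baseline_epochs):
        gabor = [e for e in baseline_epochs if e.condition == ATTEND_GABOR]
        face = [e for e in baseline_epochs if e.condition == ATTEND_FACE]
        with pytest.raises(ValueError, match="at least 10"):
            sb.AttentionDecoder(gabor[:4] + face[:4])

    def test_probability_complement(self, fitted_decoder):
        probe = sb.simulate_epoch(compact_config(), ATTEND_FACE, seed=1000)
        p = fitted_decoder.gabor_probability(probe).probability
        assert fitted_decoder.face_probability(probe) == pytest.approx(1 - p, abs=1e-12)

    def test_scores_track_condition_at_high_contrast(self, fitted_decoder):
        cfg = compact_config()
        pg = fitted_decoder.gabor_probability(
            sb.simulate_epoch(cfg, ATTEND_GABOR, seed=77)).probability
        pf = fitted_decoder.gabor_probability(
            sb.simulate_epoch(cfg, ATTEND_FACE, seed=78)).probability
        assert pg > 0.5 > pf

    def test_uncalibrated_model_refuses_probability(self, fitted_decoder, baseline_epochs):
        import copy

        broken = copy.copy(fitted_decoder)
        broken.platt = None
        with pytest.raises(NotCalibratedError):
            broken.gabor_probability(baseline_epochs[0])

    def test_summary_mentions_key_fields(self, fitted_decoder):
        text = fitted_decoder.summary()
        assert "Power bank" in text and "linear" in text and "CV accuracy" in text

    def test_save_load_roundtrip(self, fitted_decoder, baseline_epochs, tmp_path):
        fitted_decoder.save(tmp_path / "model")
        back = sb.DecoderResults.load(tmp_path / "model")
        probe = baseline_epochs[5]
        assert back.gabor_probability(probe).probability == \
            fitted_decoder.gabor_probability(probe).probability


class TestProfiling:
    def test_single_cell_grid_equals_direct_cv(self, baseline_epochs):
        cfg = sb.FeatureConfig(family="power_bank", n_harmonics=2)
        grid = sb.profile_configurations([baseline_epochs], [cfg],
                                         kernels=("linear",), seed=5)
        assert grid.n_cells == 1
        fm = sb.assemble_feature_matrix(baseline_epochs, cfg)
        mean, sd = sb.cross_validate(fm, "linear", seed=5)
        assert grid.accuracy(0, "linear") == mean
        assert grid.table.loc[0, "linear_sd"] == sd

    def test_standard_menu_size(self):
        menu = sb.standard_menu()
        assert len(menu) == 14
        assert sum(c.use_feature_selection for c in menu) == 4

    def test_empty_menu_rejected(self, baseline_epochs):
        with pytest.raises(ValueError, match="empty"):
            sb.profile_configurations([baseline_epochs], [])

    def test_power_bank_outranks_cosine_corr(self):
        """Power bank (n=3, f0=2) beats cosine corr (n=1) averaged over 10 seeds."""
        pb_accs, cc_accs = [], []
        for seed in range(10):
            eps = simulate_baseline(seed=300 + seed)
            pb = sb.assemble_feature_matrix(eps, sb.FeatureConfig(family="power_bank"))
            cc = sb.assemble_feature_matrix(
                eps, sb.FeatureConfig(family="cosine_corr", n_harmonics=1))
            pb_accs.append(sb.cross_validate(pb, "linear", seed=seed)[0])
            cc_accs.append(sb.cross_validate(cc, "linear", seed=seed)[0])
        assert np.mean(pb_accs) >= np.mean(cc_accs)
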