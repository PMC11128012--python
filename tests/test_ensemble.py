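"""Tests for bagging, the power-mean combiner and EL-APMC training."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elapmc import ensemble as ens
from elapmc import mri_features as mf
from elapmc import synthetic
from elapmc.exceptions import ConfigError, DomainError, SchemaError, VersionError

SCORES = st.lists(
    st.floats(min_value=1e-4, max_value=1.0 - 1e-4), min_size=2, max_size=12
)


def small_gaussian_data(n_per_class=20, seed=0, separation=3.0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, 4))
    X1 = rng.normal(separation, 1.0, size=(n_per_class, 4))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestBags:
    def test_half_and_half_disjoint(self):
        cfg = ens.EnsembleConfig(n_estimators=5, seed=1)
        bags = ens.make_bags(10, cfg, np.random.default_rng(1))
        for inbag, outbag in bags:
            assert len(inbag) == 5 and len(outbag) == 5
            assert not set(inbag) & set(outbag)

    def test_same_seed_gives_identical_bags(self):
        cfg = ens.EnsembleConfig(n_estimators=8, seed=3)
        a = ens.make_bags(20, cfg, np.random.default_rng(3))
        b = ens.make_bags(20, cfg, np.random.default_rng(3))
        for (i1, o1), (i2, o2) in zip(a, b):
            assert np.array_equal(i1, i2) and np.array_equal(o1, o2)

    def test_subsets_repeat_across_a_large_ensemble(self):
        # n=6 has only C(6,3)=20 distinct half-splits, so 100 draws must collide
        cfg = ens.EnsembleConfig(n_estimators=100, seed=0)
        bags = ens.make_bags(6, cfg, np.random.default_rng(0))
        keys = {tuple(i) + tuple(o) for i, o in bags}
        assert len(keys) < 100

    def test_too_small_sample_is_a_config_error(self):
        cfg = ens.EnsembleConfig(n_estimators=2)
        with pytest.raises(ConfigError):
            ens.make_bags(1, cfg, np.random.default_rng(0))


class TestSubspace:
    @pytest.mark.parametrize("nof, expected", [(8, 3), (1, 1), (16, 4), (2, 1)])
    def test_sqrt_rule_with_half_up_rounding(self, nof, expected):
        assert ens.subspace_size(nof) == expected

    def test_picked_subset_is_valid(self):
        cfg = ens.EnsembleConfig()
        sub = ens.pick_subspace(8, cfg, np.random.default_rng(0))
        assert len(sub) == 3 and len(set(sub)) == 3
        assert all(0 <= i < 8 for i in sub)

    def test_single_feature(self):
        cfg = ens.EnsembleConfig()
        assert list(ens.pick_subspace(1, cfg, np.random.default_rng(0))) == [0]


class TestBaseLearner:
    def test_separated_clouds_score_above_half(self):
        X, y = small_gaussian_data(seed=5, separation=3.0)
        coef, intercept = ens.fit_base(X, y)
        model = ens.BaseModel(
            feature_subset=np.arange(4),
            inbag_idx=np.arange(len(y)),
            outbag_idx=np.array([], dtype=int),
            coef=coef,
            intercept=intercept,
        )
        assert np.all(model.scores(X[y == 1]) > 0.5)

    def test_scores_clipped_to_open_unit_interval(self):
        X, y = small_gaussian_data(seed=2, separation=30.0)
        coef, intercept = ens.fit_base(X, y)
        model = ens.BaseModel(np.arange(4), np.arange(len(y)), np.array([], int), coef, intercept)
        s = model.scores(X)
        assert np.all(s >= 1e-6) and np.all(s <= 1 - 1e-6)

    def test_duplicate_rows_get_identical_scores(self):
        X, y = small_gaussian_data(seed=0)
        coef, intercept = ens.fit_base(X, y)
        model = ens.BaseModel(np.arange(4), np.arange(len(y)), np.array([], int), coef, intercept)
        dup = np.vstack([X[0], X[0]])
        s = model.scores(dup)
        assert s[0] == s[1]

    def test_single_class_rejected(self):
        X, _ = small_gaussian_data(seed=0)
        with pytest.raises(DomainError):
            ens.fit_base(X, np.zeros(len(X), dtype=int))


class TestPowerMean:
    def test_alpha_one_is_arithmetic_mean(self):
        assert ens.pmc_fuse([0.2, 0.4, 0.6], 1.0) == pytest.approx(0.4, abs=1e-12)

    def test_idempotence_on_equal_scores(self):
        for alpha in (-7.0, -1.0, 0.0, 1.0, 9.0):
            assert ens.pmc_fuse([0.25, 0.25], alpha) == pytest.approx(0.25, abs=1e-12)

    def test_geometric_limit(self):
        expected = (0.1 * 0.4 * 0.9) ** (1 / 3)
        assert ens.pmc_fuse([0.1, 0.4, 0.9], 0.0) == pytest.approx(expected, abs=1e-12)
        # numerically tiny alpha agrees with the closed-form limit
        for a in (1e-7, -1e-7):
            assert ens.pmc_fuse([0.1, 0.4, 0.9], a) == pytest.approx(expected, abs=1e-6)

    def test_large_alpha_approaches_min_and_max(self):
        # exact asymptotics: max * 2^(-1/alpha) and min * 2^(-1/alpha)
        assert ens.pmc_fuse([0.1, 0.9], 60.0) == pytest.approx(
            0.9 * 2 ** (-1 / 60), abs=1e-9
        )
        assert ens.pmc_fuse([0.1, 0.9], -60.0) == pytest.approx(
            0.1 * 2 ** (1 / 60), abs=1e-9
        )
        assert abs(ens.pmc_fuse([0.1, 0.9], 60.0) - 0.9) < 0.02
        assert abs(ens.pmc_fuse([0.1, 0.9], -60.0) - 0.1) < 0.02

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(DomainError):
            ens.pmc_fuse([0.2, 0.0], 1.0)

    def test_weighted_mean_with_degenerate_weight_selects_one_score(self):
        assert ens.pmc_fuse([0.2, 0.8], 2.5, weights=[1, 0]) == pytest.approx(0.2)

    def test_bad_weights_rejected(self):
        with pytest.raises(DomainError):
            ens.pmc_fuse([0.2, 0.8], 1.0, weights=[-1, 0.5])

    @settings(max_examples=150, derandomize=True)
    @given(scores=SCORES)
    def test_bounded_by_min_and_max(self, scores):
        for alpha in (-10.0, -1.0, 0.0, 1.0, 10.0):
            v = ens.pmc_fuse(scores, alpha)
            assert min(scores) - 1e-12 <= v <= max(scores) + 1e-12

    @settings(max_examples=150, derandomize=True)
    @given(scores=SCORES)
    def test_monotone_in_alpha(self, scores):
        grid = [-5.0, -1.0, 0.0, 1.0, 5.0]
        vals = [ens.pmc_fuse(scores, a) for a in grid]
        if max(scores) - min(scores) > 1e-6:
            assert all(b > a for a, b in zip(vals, vals[1:]))
        else:
            assert all(abs(b - a) < 1e-6 for a, b in zip(vals, vals[1:]))

    def test_closed_form_equivalences_alpha_minus_one(self):
        scores = np.array([0.2, 0.5, 0.8])
        harmonic = len(scores) / np.sum(1.0 / scores)
        assert ens.pmc_fuse(scores, -1.0) == pytest.approx(harmonic, abs=1e-12)


def brute_force_threshold_error(mu, fused, labels, hi_class):
    """Per-sample error count of the rule: predict hi iff score >= mu."""
    wrong = 0
    for s, lbl in zip(fused, labels):
        pred = hi_class if s >= mu else 1 - hi_class
        wrong += pred != lbl
    return wrong / len(labels)


class TestEstimatePe:
    def test_perfect_separation_gives_zero(self):
        fused = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert ens.estimate_pe(0.5, fused, labels) == 0.0

    def test_hand_counted_example(self):
        fused = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert ens.estimate_pe(0.5, fused, labels) == 0.0
        assert ens.estimate_pe(0.7, fused, labels) == pytest.approx(0.25)

    def test_identical_distributions_give_half(self):
        fused = np.concatenate([np.linspace(0.1, 0.9, 50)] * 2)
        labels = np.array([0] * 50 + [1] * 50)
        assert ens.estimate_pe(0.5, fused, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            fused = rng.uniform(0.01, 0.99, size=n)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            mu = float(rng.uniform(0.0, 1.0))
            m0, m1 = fused[labels == 0].mean(), fused[labels == 1].mean()
            hi = 1 if m1 >= m0 else 0
            expected = brute_force_threshold_error(mu, fused, labels, hi)
            assert ens.estimate_pe(mu, fused, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            ens.estimate_pe(0.5, np.array([0.1, 0.2]), np.array([1, 1]))


class TestOptimizePmc:
    def test_identical_bases_reduce_to_single_classifier_error(self, rng):
        S, labels, _ = synthetic.gen_fusion_testbed(80, 6, "identical", seed=4)
        pmc = ens.optimize_pmc(S, labels, ens.EnsembleConfig(seed=4, optimizer_budget=80))
        _, best_single = ens._best_mu(S[:, 0], labels, hi_class=1)
        assert pmc.achieved_pe == pytest.approx(best_single, abs=1e-12)

    def test_dominates_arithmetic_mean_on_outlier_regime(self):
        S, labels, info = synthetic.gen_fusion_testbed(120, 5, "outlier-min", seed=0)
        pmc = ens.optimize_pmc(S, labels, ens.EnsembleConfig(seed=0, optimizer_budget=150))
        assert pmc.achieved_pe <= info["pe_alpha1"]
        assert pmc.achieved_pe <= info["pe_alpha1"] - info["margin"] + 1e-12

    def test_deterministic_under_seed(self):
        S, labels, _ = synthetic.gen_fusion_testbed(60, 4, "independent", seed=2)
        cfg = ens.EnsembleConfig(seed=9, optimizer_budget=60)
        a = ens.optimize_pmc(S, labels, cfg)
        b = ens.optimize_pmc(S, labels, cfg)
        assert (a.alpha_opt, a.mu_opt, a.achieved_pe) == (b.alpha_opt, b.mu_opt, b.achieved_pe)

    def test_tiny_budget_rejected(self):
        S, labels, _ = synthetic.gen_fusion_testbed(20, 3, "independent", seed=0)
        with pytest.raises(ConfigError):
            ens.optimize_pmc(S, labels, ens.EnsembleConfig(optimizer_budget=5))


@pytest.fixture(scope="module")
def trained_model():
    X, y = small_gaussian_data(n_per_class=20, seed=7)
    cfg = ens.EnsembleConfig(n_estimators=20, seed=7, optimizer_budget=40)
    return ens.fit(X, y, cfg, positive_class=1), X, y


class TestFitPredict:
    def test_smoke_and_invariants(self, trained_model):
        model, X, y = trained_model
        assert len(model.base_models) == 20
        assert sum(model.pmc.priors) == pytest.approx(1.0)
        assert 0.0 <= model.pmc.achieved_pe <= 1.0
        lo, hi = model.config.alpha_bounds
        assert lo <= model.pmc.alpha_opt <= hi
        for m in model.base_models:
            assert not set(m.inbag_idx) & set(m.outbag_idx)
            assert len(m.feature_subset) == ens.subspace_size(X.shape[1])

    def test_single_class_labels_rejected(self):
        X, _ = small_gaussian_data()
        with pytest.raises(DomainError):
            ens.fit(X, np.ones(len(X), dtype=int))

    def test_training_error_consistent_with_outbag_estimate(self, trained_model):
        model, X, y = trained_model
        err = np.mean(ens.predict(model, X) != y)
        assert err == pytest.approx(model.pmc.achieved_pe, abs=0.1)

    def test_duplicated_sample_predicts_identically(self, trained_model):
        model, X, _ = trained_model
        dup = np.vstack([X[3], X[3]])
        pred = ens.predict(model, dup)
        assert pred[0] == pred[1]

    def test_fused_score_within_base_score_envelope(self, trained_model):
        model, X, _ = trained_model
        S = np.column_stack([m.scores(X) for m in model.base_models])
        fused = ens.predict_score(model, X)
        assert np.all(fused >= S.min(axis=1) - 1e-12)
        assert np.all(fused <= S.max(axis=1) + 1e-12)

    def test_full_determinism_under_seed(self):
        X, y = small_gaussian_data(n_per_class=15, seed=11)
        cfg = ens.EnsembleConfig(n_estimators=10, seed=5, optimizer_budget=30)
        m1 = ens.fit(X, y, cfg)
        m2 = ens.fit(X, y, cfg)
        assert m1.pmc.alpha_opt == m2.pmc.alpha_opt
        assert np.array_equal(ens.predict_score(m1, X), ens.predict_score(m2, X))

    def test_feature_mismatch_rejected(self, trained_model):
        model, X, _ = trained_model
        with pytest.raises(SchemaError):
            ens.predict(model, X[:, :3])

    def test_weighted_fit_runs(self):
        X, y = small_gaussian_data(n_per_class=15, seed=3)
        cfg = ens.EnsembleConfig(n_estimators=10, seed=3, optimizer_budget=30, use_weights=True)
        model = ens.fit(X, y, cfg)
        assert model.weights is not None
        assert model.weights.sum() == pytest.approx(1.0)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, trained_model, tmp_path):
        model, X, _ = trained_model
        path = tmp_path / "model.json"
        ens.save_model(model, path)
        back = ens.load_model(path)
        assert np.array_equal(ens.predict(back, X), ens.predict(model, X))
        assert np.allclose(ens.predict_score(back, X), ens.predict_score(model, X))

    def test_truncated_file_fails_to_parse(self, trained_model, tmp_path):
        model, _, _ = trained_model
        path = tmp_path / "model.json"
        ens.save_model(model, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(json.JSONDecodeError):
            ens.load_model(path)

    def test_version_mismatch_rejected(self, trained_model, tmp_path):
        model, _, _ = trained_model
        path = tmp_path / "model.json"
        ens.save_model(model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(VersionError):
            ens.load_model(path)

    def test_parameters_are_live_after_load(self, trained_model, tmp_path):
        model, X, _ = trained_model
        path = tmp_path / "model.json"
        ens.save_model(model, path)
        back = ens.load_model(path)
        scores_before = ens.predict_score(back, X)
        back.pmc.alpha_opt = back.pmc.alpha_opt + 15.0
        scores_after = ens.predict_score(back, X)
        assert not np.allclose(scores_before, scores_after)
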