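"""Engine-level unit and property tests: similarity, associations, updates,
activation, and the fit loop checked against closed forms and an
independently coded textbook EM oracle."""

import numpy as np
import pytest

from nmfdl.core import (
    DataField,
    FitConfig,
    InputError,
    ModelComponent,
    StateError,
    activate_deactivate,
    associations,
    conditional_similarity,
    fit,
    penalized_similarity,
    total_log_similarity,
    update_parameters,
    update_rates,
)
from nmfdl.families import BernoulliFamily, GaussianMeanFamily, UniformClutterFamily


def gauss_component(mean, var, r=1.0, index=0, status="active", family=None):
    family = family or GaussianMeanFamily(np.atleast_1d(mean).size)
    return ModelComponent(index, family, np.atleast_1d(np.asarray(mean, float)),
                          float(var), float(r), status)


# ---------------------------------------------------------------------------
# conditional similarity (Eq. 1 ingredients)
# ---------------------------------------------------------------------------


class TestConditionalSimilarity:
    def test_gaussian_peak_density_is_one_at_special_variance(self):
        # scalar normal density at its mean with sigma^2 = 1/(2 pi) equals 1
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.7, 1.0 / (2 * np.pi), family=fam)
        assert conditional_similarity(fam, m, [0.7]) == pytest.approx(1.0, rel=1e-12)

    def test_gaussian_tail_value(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(2.0, 1.0, family=fam)
        expected = (2 * np.pi) ** -0.5 * np.exp(-2.0)  # ~0.05399
        assert conditional_similarity(fam, m, [0.0]) == pytest.approx(expected, rel=1e-12)
        assert conditional_similarity(fam, m, [0.0]) == pytest.approx(0.05399, abs=5e-6)

    def test_uniform_clutter_density(self):
        fam = UniformClutterFamily(lo=0.0, hi=4.0)
        m = ModelComponent(0, fam, np.array([0.0, 4.0]), 1.0, 1.0)
        for x in (0.0, 1.3, 4.0):
            assert conditional_similarity(fam, m, [x]) == pytest.approx(0.25)
        assert conditional_similarity(fam, m, [4.5]) == 0.0

    def test_dimension_mismatch_and_bad_spread_raise(self):
        fam = GaussianMeanFamily(2)
        m = gauss_component([0.0, 0.0], 1.0, family=fam)
        with pytest.raises(InputError):
            conditional_similarity(fam, m, [0.0])
        m_bad = gauss_component([0.0, 0.0], -1.0, family=fam)
        with pytest.raises(InputError):
            conditional_similarity(fam, m_bad, [0.0, 0.0])


# ---------------------------------------------------------------------------
# total log-similarity (Eq. 1)
# ---------------------------------------------------------------------------


class TestTotalLogSimilarity:
    def test_all_ones_gives_zero(self):
        # a single model with unit density everywhere: log of a product of ones
        fam = UniformClutterFamily(lo=0.0, hi=1.0)
        m = ModelComponent(0, fam, np.array([0.0, 1.0]), 1.0, 1.0)
        data = DataField(np.array([[0.2], [0.5], [0.9]]))
        assert total_log_similarity(data, [m]) == pytest.approx(0.0, abs=1e-12)

    def test_two_model_hand_value(self):
        # r = 0.5 each, l = 0.2 and 0.6 for one datum -> log 0.4
        f1 = UniformClutterFamily(lo=0.0, hi=5.0)  # density 0.2
        f2 = UniformClutterFamily(lo=0.0, hi=5.0 / 3.0)  # density 0.6
        m1 = ModelComponent(0, f1, np.array([0.0, 5.0]), 1.0, 0.5)
        m2 = ModelComponent(1, f2, np.array([0.0, 5.0 / 3.0]), 1.0, 0.5)
        data = DataField(np.array([[0.5]]))
        assert total_log_similarity(data, [m1, m2]) == pytest.approx(np.log(0.4), rel=1e-12)

    def test_matches_bruteforce_product_sum(self, rng):
        # N = 3 data, M = 2 Gaussian models: term-by-term oracle
        fam = GaussianMeanFamily(2)
        X = rng.normal(size=(3, 2))
        m1 = gauss_component([0.0, 1.0], 0.7, r=0.3, family=fam)
        m2 = gauss_component([2.0, -1.0], 1.4, r=0.7, index=1, family=fam)
        expected = 0.0
        for x in X:
            tot = 0.0
            for m in (m1, m2):
                d = len(x)
                dens = (2 * np.pi * m.spread) ** (-d / 2) * np.exp(
                    -np.sum((x - m.params) ** 2) / (2 * m.spread)
                )
                tot += m.r * dens
            expected += np.log(tot)
        got = total_log_similarity(DataField(X), [m1, m2])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_active_models_raises(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, status="dormant", family=fam)
        with pytest.raises(StateError):
            total_log_similarity(DataField(np.zeros((2, 1))), [m])


# ---------------------------------------------------------------------------
# skeptic penalty
# ---------------------------------------------------------------------------


class TestPenalizedSimilarity:
    def test_no_free_params_is_identity(self):
        fam = UniformClutterFamily(lo=0.0, hi=1.0)
        m = ModelComponent(0, fam, np.array([0.0, 1.0]), 1.0, 1.0)
        assert penalized_similarity(-3.2, [m], 10) == pytest.approx(-3.2)

    def test_aic_like_value(self):
        # loglik = -10, k = 4 free params, kappa = 1 -> -14
        fam = GaussianMeanFamily(3)  # 3 + 1 free params
        m = gauss_component([0.0, 0.0, 0.0], 1.0, family=fam)
        assert penalized_similarity(-10.0, [m], 50) == pytest.approx(-14.0)

    def test_extra_model_decreases_by_its_param_count(self):
        fam = GaussianMeanFamily(2)
        m1 = gauss_component([0.0, 0.0], 1.0, family=fam)
        m2 = gauss_component([1.0, 1.0], 1.0, index=1, family=fam)
        one = penalized_similarity(-5.0, [m1], 20)
        two = penalized_similarity(-5.0, [m1, m2], 20)
        assert one - two == pytest.approx(fam.n_free_params)

    def test_bic_is_steeper_for_smaller_n(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, family=fam)
        # BIC kappa = log(N)/2 grows with N; per the steeper-for-small-N
        # requirement the penalty share relative to the data size shrinks
        p_small = -penalized_similarity(0.0, [m], 10, penalty="bic") / 10
        p_large = -penalized_similarity(0.0, [m], 1000, penalty="bic") / 1000
        assert p_small > p_large

    def test_bad_n_raises(self):
        with pytest.raises(InputError):
            penalized_similarity(-1.0, [], 0)


# ---------------------------------------------------------------------------
# associations (Eq. 2)
# ---------------------------------------------------------------------------


class TestAssociations:
    def test_single_model_all_ones(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, family=fam)
        f = associations(DataField(np.array([[0.0], [3.0]])), [m])
        assert np.allclose(f, 1.0)

    def test_symmetric_models_split_evenly(self):
        fam = GaussianMeanFamily(1)
        m1 = gauss_component(-1.0, 1.0, r=0.5, family=fam)
        m2 = gauss_component(1.0, 1.0, r=0.5, index=1, family=fam)
        f = associations(DataField(np.array([[0.0]])), [m1, m2])
        assert np.allclose(f, 0.5)

    def test_logistic_hand_value(self):
        # x = 0, means 0 and 2, sigma^2 = 1 -> f(1|x) = 1 / (1 + e^-2)
        fam = GaussianMeanFamily(1)
        m1 = gauss_component(0.0, 1.0, r=0.5, family=fam)
        m2 = gauss_component(2.0, 1.0, r=0.5, index=1, family=fam)
        f = associations(DataField(np.array([[0.0]])), [m1, m2])
        assert f[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), rel=1e-12)

    def test_columns_sum_to_one(self, rng):
        fam = GaussianMeanFamily(2)
        models = [
            gauss_component(rng.normal(size=2), float(rng.uniform(0.5, 2.0)),
                            r=float(r), index=i, family=fam)
            for i, r in enumerate(rng.dirichlet(np.ones(4)))
        ]
        X = rng.normal(scale=3.0, size=(40, 2))
        f = associations(DataField(X), models)
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-9)
        assert np.all((f >= 0) & (f <= 1))


# ---------------------------------------------------------------------------
# fixed-point updates and rates
# ---------------------------------------------------------------------------


class TestUpdates:
    def test_gaussian_weighted_mean(self):
        fam = GaussianMeanFamily(1, anneal=0.0)
        m = gauss_component(5.0, 4.0, family=fam)
        data = DataField(np.array([[0.0], [2.0]]))
        out = update_parameters(data, [m], np.array([[1.0, 1.0]]))
        assert out[0].params[0] == pytest.approx(1.0)

    def test_bernoulli_weighted_mle(self):
        fam = BernoulliFamily(1)
        m = ModelComponent(0, fam, np.array([0.5]), 1.0, 1.0)
        data = DataField(np.array([[1.0], [1.0], [0.0]]), binary=True)
        out = update_parameters(data, [m], np.array([[1.0, 1.0, 1.0]]))
        assert out[0].params[0] == pytest.approx(2.0 / 3.0)

    def test_starved_model_left_unchanged_and_flagged(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(5.0, 4.0, family=fam)
        data = DataField(np.array([[0.0], [2.0]]))
        out = update_parameters(data, [m], np.array([[0.0, 0.0]]))
        assert out[0].params[0] == pytest.approx(5.0)
        assert out[0].flagged

    def test_update_step_never_decreases_similarity(self, two_cluster_1d):
        # one E/M sweep on a 2-model instance matches EM monotonicity
        fam = GaussianMeanFamily(1, anneal=0.0)
        models = [gauss_component(1.0, 4.0, r=0.5, family=fam),
                  gauss_component(6.0, 4.0, r=0.5, index=1, family=fam)]
        before = total_log_similarity(two_cluster_1d, models)
        f = associations(two_cluster_1d, models)
        models = update_parameters(two_cluster_1d, models, f)
        models = update_rates(f, len(two_cluster_1d), models)
        after = total_log_similarity(two_cluster_1d, models)
        assert after >= before - 1e-10 * abs(before)

    def test_rates_single_model(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, family=fam)
        out = update_rates(np.ones((1, 6)) / 1.0, 6, [m])
        assert out[0].r == pytest.approx(1.0)

    def test_rates_half_and_half_and_normalization(self, rng):
        fam = GaussianMeanFamily(1)
        models = [gauss_component(0.0, 1.0, family=fam),
                  gauss_component(1.0, 1.0, index=1, family=fam)]
        f = np.zeros((2, 10))
        f[0, :5] = 1.0
        f[1, 5:] = 1.0
        out = update_rates(f, 10, models)
        assert [m.r for m in out] == pytest.approx([0.5, 0.5])
        f_rand = rng.random((2, 10))
        f_rand /= f_rand.sum(axis=0)
        out = update_rates(f_rand, 10, models)
        assert sum(m.r for m in out) == pytest.approx(1.0, abs=1e-9)


class TestActivateDeactivate:
    def test_dormant_above_threshold_activates(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, r=0.2, status="dormant", family=fam)
        keep = gauss_component(1.0, 1.0, r=0.8, index=1, family=fam)
        out = activate_deactivate([m, keep], 0.1)
        assert out[0].status == "active"

    def test_active_below_threshold_goes_dormant(self):
        fam = GaussianMeanFamily(1)
        m = gauss_component(0.0, 1.0, r=0.001, family=fam)
        keep = gauss_component(1.0, 1.0, r=0.999, index=1, family=fam)
        out = activate_deactivate([m, keep], 0.01)
        assert out[0].status == "dormant"

    def test_highest_rate_model_is_retained(self):
        fam = GaussianMeanFamily(1)
        models = [gauss_component(0.0, 1.0, r=0.004, index=0, family=fam),
                  gauss_component(1.0, 1.0, r=0.006, index=1, family=fam)]
        out = activate_deactivate(models, 0.5)
        assert [m.status for m in out] == ["dormant", "active"]

    def test_bad_threshold_raises(self):
        with pytest.raises(InputError):
            activate_deactivate([], 1.5)


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------


def naive_em_gaussian(X, means, variances, weights, n_iter):
    """Independently coded textbook EM for a 1-D Gaussian mixture.

    Plain loops, no engine code; returns per-iteration log-likelihoods and
    the final parameters.
    """
    means = list(map(float, means))
    variances = list(map(float, variances))
    weights = list(map(float, weights))
    M = len(means)
    lls = []
    for _ in range(n_iter):
        resp = np.zeros((len(X), M))
        for n, x in enumerate(X[:, 0]):
            for m in range(M):
                resp[n, m] = weights[m] * (
                    (2 * np.pi * variances[m]) ** -0.5
                    * np.exp(-((x - means[m]) ** 2) / (2 * variances[m]))
                )
        ll = float(np.sum(np.log(resp.sum(axis=1))))
        lls.append(ll)
        resp /= resp.sum(axis=1, keepdims=True)
        for m in range(M):
            wm = resp[:, m].sum()
            means[m] = float(resp[:, m] @ X[:, 0] / wm)
            variances[m] = float(resp[:, m] @ (X[:, 0] - means[m]) ** 2 / wm)
            weights[m] = float(wm / len(X))
    return lls, means, variances, weights


class TestFit:
    def test_single_gaussian_recovers_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(4.0, 1.0, (200, 1))
        cfg = FitConfig(n_models_init=1, n_dormant=0, max_iter=200)
        st = fit(DataField(X), GaussianMeanFamily(1), cfg, seed=0)
        act = [m for m in st.models if m.status == "active"]
        se = 1.0 / np.sqrt(200)
        assert len(act) == 1
        assert abs(act[0].params[0] - X.mean()) < 1e-6  # exact MLE
        assert abs(act[0].params[0] - 4.0) < 3 * se

    def test_infinite_tolerance_returns_unconverged_initial_state(self, two_cluster_1d):
        cfg = FitConfig(n_models_init=2, n_dormant=0, tol=np.inf)
        st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=0)
        assert st.iteration == 0
        assert not st.converged
        assert len(st.loglik_trace) == 1

    def test_matches_bruteforce_em_trajectory(self, two_cluster_1d):
        # fixed roster, no annealing, explicit init: the engine must follow
        # the textbook EM trajectory step for step to 1e-6
        fam = GaussianMeanFamily(1, anneal=0.0, var_floor=0.0)
        init = [gauss_component(1.0, 4.0, r=0.5, family=fam),
                gauss_component(6.0, 9.0, r=0.5, index=1, family=fam)]
        cfg = FitConfig(n_models_init=2, n_dormant=0, max_iter=25, tol=0.0,
                        merge=False, penalty="none", activation_threshold=1e-12)
        st = fit(two_cluster_1d, fam, cfg, seed=0,
                 init_models=[m.copy() for m in init])
        lls, means, variances, weights = naive_em_gaussian(
            two_cluster_1d.X, [1.0, 6.0], [4.0, 9.0], [0.5, 0.5], 26)
        # trace[i] is the log-similarity after i engine iterations, which the
        # oracle sees at the start of its iteration i
        for i in range(len(st.loglik_trace)):
            assert st.loglik_trace[i] == pytest.approx(lls[i], abs=1e-6)
        act = sorted((m for m in st.models if m.status == "active"),
                     key=lambda m: m.params[0])
        assert act[0].params[0] == pytest.approx(min(means), abs=1e-6)
        assert act[1].params[0] == pytest.approx(max(means), abs=1e-6)

    def test_two_clusters_recovered(self, two_cluster_1d):
        cfg = FitConfig(n_models_init=2, n_dormant=2, max_iter=300)
        st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=5)
        act = sorted((m for m in st.models if m.status == "active"),
                     key=lambda m: m.params[0])
        assert len(act) == 2
        assert act[0].params[0] == pytest.approx(0.0, abs=0.8)
        assert act[1].params[0] == pytest.approx(8.0, abs=0.8)

    def test_dormant_model_activates_on_orphan_cluster(self, two_cluster_1d):
        # one initial model locks a cluster; a dormant vague model must pick
        # up the orphan cluster's mass and activate
        cfg = FitConfig(n_models_init=1, n_dormant=3, max_iter=300)
        st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=2)
        act = sorted((m for m in st.models if m.status == "active"),
                     key=lambda m: m.params[0])
        assert len(act) == 2
        assert act[0].params[0] == pytest.approx(0.0, abs=0.8)
        assert act[1].params[0] == pytest.approx(8.0, abs=0.8)

    def test_identical_seeds_bit_identical(self, two_cluster_1d):
        cfg = FitConfig(n_models_init=2, n_dormant=2, max_iter=100)
        a = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=11)
        b = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=11)
        assert np.array_equal(a.loglik_trace, b.loglik_trace)
        for ma, mb in zip(a.models, b.models):
            assert np.array_equal(ma.params, mb.params)
            assert ma.spread == mb.spread and ma.r == mb.r

    def test_monotone_trace_outside_structural_iterations(self, two_cluster_1d):
        for seed in range(5):
            cfg = FitConfig(n_models_init=3, n_dormant=2, max_iter=300)
            st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=seed)
            struct = set(st.structural_iterations)
            d = np.diff(st.loglik_trace)
            for i, delta in enumerate(d):
                if i in struct:  # dip allowed only where the roster changed
                    continue
                assert delta >= -1e-8 * max(1.0, abs(st.loglik_trace[i]))

    def test_vague_to_crisp_spread_and_entropy(self, two_cluster_1d):
        cfg = FitConfig(n_models_init=2, n_dormant=0, max_iter=300,
                        record_history=True)
        st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=5)
        spreads = np.array([[m.spread for m in snap if m.status == "active"]
                            for snap in st.history])
        # eventually non-increasing per model (after burn-in)
        tail = spreads[len(spreads) // 3 :]
        assert np.all(np.diff(tail, axis=0) <= 1e-9)
        ent0 = _mean_assoc_entropy(two_cluster_1d, st.history[0])
        ent1 = _mean_assoc_entropy(two_cluster_1d, st.history[-1])
        assert ent1 <= ent0 + 1e-12

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(InputError):
            FitConfig.from_dict({"n_models_init": 2, "bogus": 1})

    def test_fit_state_json_roundtrip_fields(self, two_cluster_1d, tmp_path):
        cfg = FitConfig(n_models_init=2, n_dormant=1, max_iter=50)
        st = fit(two_cluster_1d, GaussianMeanFamily(1), cfg, seed=0)
        path = tmp_path / "fit.json"
        st.save_json(path)
        import json

        d = json.loads(path.read_text())
        assert d["iteration"] == st.iteration
        assert d["loglik_trace"] == pytest.approx(list(st.loglik_trace))
        assert len(d["models"]) == len(st.models)
        assert {m["status"] for m in d["models"]} <= {"active", "dormant"}


def _mean_assoc_entropy(data, models):
    act = [m for m in models if m.status == "active"]
    f = associations(data, act)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(f > 0, f * np.log(f), 0.0).sum(axis=0)
    return float(h.mean())
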