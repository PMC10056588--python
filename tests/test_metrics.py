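"""Recovery metrics and model-comparison index tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dinmix as dm


class TestBiasRmse:
    @pytest.mark.parametrize(
        "est, truth, bias, rmse",
        [
            ([0.2, 0.2], 0.1, 0.1, 0.1),
            ([0.0, 0.2], 0.1, 0.0, 0.1),
        ],
    )
    def test_examples(self, est, truth, bias, rmse):
        b, r = dm.bias_rmse(np.array(est), np.array(truth))
        assert b == pytest.approx(bias)
        assert r == pytest.approx(rmse)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        est = rng.normal(0.5, 0.1, size=(30, 4))
        tru = rng.normal(0.5, 0.05, size=4)
        b, r = dm.bias_rmse(est, tru)
        err = est - tru
        assert b == pytest.approx(err.sum(axis=0) / 30)
        assert r == pytest.approx(np.sqrt((err**2).sum(axis=0) / 30))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dm.bias_rmse(np.zeros((3, 2)), np.zeros(5))


class TestClassificationRates:
    def test_perfect_and_complement(self):
        rng = np.random.default_rng(1)
        A = rng.integers(0, 2, size=(50, 5))
        assert dm.accr(A, A) == pytest.approx(np.ones(5))
        assert dm.pccr(A, A) == 1.0
        assert dm.accr(1 - A, A) == pytest.approx(np.zeros(5))
        assert dm.pccr(1 - A, A) == 0.0

    def test_one_wrong_cell(self):
        A = np.zeros((10, 3), dtype=int)
        B = A.copy()
        B[0, 0] = 1
        assert dm.pccr(B, A) == pytest.approx(0.9)

    def test_matches_loop_count(self):
        rng = np.random.default_rng(2)
        est = rng.integers(0, 2, size=(100, 5))
        tru = rng.integers(0, 2, size=(100, 5))
        acc = dm.accr(est, tru)
        for k in range(5):
            count = sum(est[n, k] == tru[n, k] for n in range(100))
            assert acc[k] == pytest.approx(count / 100)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pccr_bounded_by_accr(self, seed):
        """Exact-profile agreement implies elementwise agreement, so the
        profile rate can never exceed any attribute rate."""
        rng = np.random.default_rng(seed)
        est = rng.integers(0, 2, size=(40, 4))
        tru = rng.integers(0, 2, size=(40, 4))
        assert dm.pccr(est, tru) <= dm.accr(est, tru).min() + 1e-12

    def test_replication_stacks(self):
        rng = np.random.default_rng(3)
        est = rng.integers(0, 2, size=(3, 20, 4))
        tru = rng.integers(0, 2, size=(3, 20, 4))
        flat_acc = dm.accr(est.reshape(60, 4), tru.reshape(60, 4))
        assert dm.accr(est, tru) == pytest.approx(flat_acc)


class TestProfileProportionRmse:
    def test_exact_estimates_are_zero(self):
        tru = np.full(32, 1 / 32)
        per, mean = dm.profile_proportion_rmse(np.tile(tru, (5, 1)), tru)
        assert per == pytest.approx(np.zeros(32))
        assert mean == 0.0

    def test_single_offset_pair(self):
        tru = np.full(32, 1 / 32)
        est = tru.copy()
        est[0] += 0.02
        est[1] -= 0.02
        per, mean = dm.profile_proportion_rmse(est[None], tru)
        assert per[0] == pytest.approx(0.02)
        assert per[1] == pytest.approx(0.02)
        assert mean == pytest.approx(0.04 / 32)

    def test_matches_loop(self):
        rng = np.random.default_rng(4)
        tru = rng.dirichlet(np.ones(8))
        est = rng.dirichlet(np.ones(8) * 30, size=6)
        per, mean = dm.profile_proportion_rmse(est, tru)
        for c in range(8):
            expected = np.sqrt(np.mean([(est[r, c] - tru[c]) ** 2 for r in range(6)]))
            assert per[c] == pytest.approx(expected)
        assert mean == pytest.approx(per.mean())

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            dm.profile_proportion_rmse(np.array([[0.5, 0.6]]), np.array([0.5, 0.5]))


def _point_mass_draws(Y, Q, params, alphas):
    """PosteriorDraws in which every retained draw is identical."""
    K = Q.shape[1]
    profiles = dm.all_profiles(K)
    classes = (np.asarray(alphas, dtype=np.int64) @ (1 << np.arange(K))).astype(
        np.uint8
    )
    T = 12
    g = np.array([p.g for p in params])
    s = np.array([p.s for p in params])
    tau = np.array([p.tau for p in params])
    return dm.PosteriorDraws(
        model="dinmix",
        Q=np.asarray(Q, dtype=np.int8),
        profiles=profiles,
        params={
            "g": np.tile(g, (1, T, 1)),
            "s": np.tile(s, (1, T, 1)),
            "tau": np.tile(tau, (1, T, 1, 1)),
        },
        alpha=np.tile(classes, (1, T, 1)),
        pi=np.full((1, T, 2**K), 1 / 2**K),
        acceptance={},
    )


class TestFitIndices:
    @pytest.fixture(scope="class")
    def point_mass(self):
        rng = np.random.default_rng(5)
        Q = np.array([[1, 0], [0, 1], [1, 1], [1, 1], [0, 1]])
        params = [
            dm.DinmixItemParams.for_item(0.1, 0.15, (0.5, 0.3, 0.2), Q[i])
            for i in range(5)
        ]
        alphas = rng.integers(0, 2, size=(20, 2))
        Y = dm.simulate_responses(["dinmix"] * 5, params, Q, alphas, rng)
        return Y, Q, params, alphas

    def test_point_mass_posterior(self, point_mass):
        """Identical draws: zero effective parameters, DIC equals the
        deviance, and every CPO equals the plain likelihood."""
        Y, Q, params, alphas = point_mass
        draws = _point_mass_draws(Y, Q, params, alphas)
        idx = dm.fit_indices(draws, Y)
        deviance = -2.0 * dm.log_likelihood(Y, Q, params, alphas, "dinmix")
        assert idx.effective_parameters == pytest.approx(0.0, abs=1e-6)
        assert idx.dic == pytest.approx(deviance, abs=1e-6)
        assert idx.test_lcpo2 == pytest.approx(deviance, abs=1e-6)

    def test_item_lcpo_sums_to_test_level(self, small_fit):
        data, draws, _ = small_fit
        idx = dm.fit_indices(draws, data.Y)
        assert idx.test_lcpo2 == pytest.approx(idx.item_lcpo2.sum())

    def test_harmonic_mean_against_naive(self):
        """The log-space CPO accumulation reproduces a naive arithmetic
        harmonic mean over a 10-draw toy posterior."""
        rng = np.random.default_rng(6)
        Q = np.array([[1]], dtype=np.int8)
        Y = np.array([[1], [0], [1]])
        T = 10
        g = rng.uniform(0.1, 0.3, size=(1, T, 1))
        s = rng.uniform(0.1, 0.3, size=(1, T, 1))
        classes = rng.integers(0, 2, size=(1, T, 3)).astype(np.uint8)
        draws = dm.PosteriorDraws(
            model="dina",
            Q=Q,
            profiles=dm.all_profiles(1),
            params={"g": g, "s": s},
            alpha=classes,
            pi=np.full((1, T, 2), 0.5),
            acceptance={},
        )
        idx = dm.fit_indices(draws, Y)
        # naive recomputation
        like = np.empty((T, 3, 1))
        for t in range(T):
            for n in range(3):
                a = classes[0, t, n]
                p = (1 - s[0, t, 0]) if a == 1 else g[0, t, 0]
                like[t, n, 0] = p if Y[n, 0] == 1 else 1 - p
        cpo = 1.0 / (1.0 / like).mean(axis=0)
        expected = -2.0 * np.log(cpo).sum()
        assert idx.test_lcpo2 == pytest.approx(expected)

    def test_metrics_invariant_to_person_order(self, point_mass):
        Y, Q, params, alphas = point_mass
        perm = np.random.default_rng(7).permutation(len(Y))
        a = dm.fit_indices(_point_mass_draws(Y, Q, params, alphas), Y)
        b = dm.fit_indices(
            _point_mass_draws(Y[perm], Q, params, alphas[perm]), Y[perm]
        )
        assert a.dic == pytest.approx(b.dic)
        assert a.test_lcpo2 == pytest.approx(b.test_lcpo2)

    def test_dic_against_two_pass_recomputation(self, small_fit):
        """DIC from the one-pass routine matches an independent two-pass
        implementation built from the stored draws."""
        data, draws, summary = small_fit
        idx = dm.fit_indices(draws, data.Y)
        # pass 1: mean deviance over draws
        g = draws.stacked("g")
        s = draws.stacked("s")
        tau = draws.stacked("tau")
        classes = draws.stacked("alpha")
        devs = []
        for t in range(classes.shape[0]):
            params = [
                dm.DinmixItemParams(g[t, i], s[t, i], tuple(tau[t, i]))
                for i in range(data.Q.n_items)
            ]
            alph = draws.profiles[classes[t]]
            devs.append(-2 * dm.log_likelihood(data.Y, data.Q, params, alph, "dinmix"))
        dbar = np.mean(devs)
        # pass 2: plug-in deviance at posterior means / modal profiles
        params_hat = [
            dm.DinmixItemParams(
                g[:, i].mean(), s[:, i].mean(), tuple(tau[:, i].mean(axis=0))
            )
            for i in range(data.Q.n_items)
        ]
        d_hat = -2 * dm.log_likelihood(
            data.Y, data.Q, params_hat, summary.modal_profiles, "dinmix"
        )
        assert idx.dic == pytest.approx(2 * dbar - d_hat, rel=1e-9)
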