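"""Response-function unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dinmix as dm
from dinmix.models import all_profiles, pattern_probabilities, required_subsets

PROFILES3 = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
             (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]


class TestLatentResponses:
    @pytest.mark.parametrize(
        "rule, alpha, q, expected",
        [
            (dm.latent_conjunctive, (1, 1, 1), (1, 1, 1), 1.0),
            (dm.latent_conjunctive, (1, 0, 0), (1, 1, 1), 0.0),
            (dm.latent_conjunctive, (1, 0, 1), (1, 0, 1), 1.0),
            (dm.latent_disjunctive, (0, 0, 0), (1, 1, 1), 0.0),
            (dm.latent_disjunctive, (1, 0, 0), (1, 1, 1), 1.0),
            (dm.latent_disjunctive, (0, 1, 0), (1, 0, 1), 0.0),
            (dm.latent_ratio, (1, 0, 0), (1, 1, 1), 1 / 3),
            (dm.latent_ratio, (1, 1, 1), (1, 1, 1), 1.0),
            (dm.latent_ratio, (1, 1, 0), (1, 1, 1), 2 / 3),
        ],
    )
    def test_condensation_rules(self, rule, alpha, q, expected):
        assert rule(np.array(alpha), np.array(q)) == pytest.approx(expected)

    def test_conjunctive_matches_brute_force(self):
        """Only profiles mastering every required attribute condense to 1."""
        q = np.array([1, 0, 1])
        for alpha in all_profiles(3):
            expected = float(all(alpha[k] == 1 for k in (0, 2)))
            assert dm.latent_conjunctive(alpha, q) == expected

    def test_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            dm.latent_conjunctive(np.array([1, 0]), np.array([1, 0, 1]))
        with pytest.raises(ValueError, match="no attribute"):
            dm.latent_ratio(np.array([1, 0]), np.array([0, 0]))


class TestMixedResponse:
    def test_worked_example_mix(self):
        psi = dm.mixed_latent_response((1, 0, 0), (1, 1, 1), (0.8, 0.1, 0.1))
        assert psi == pytest.approx(0.8 * 0 + 0.1 * 1 + 0.1 / 3)

    def test_equal_weights(self):
        psi = dm.mixed_latent_response((1, 1, 0), (1, 1, 1), (1 / 3, 1 / 3, 1 / 3))
        assert psi == pytest.approx(5 / 9)

    def test_full_mastery_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tau = rng.dirichlet(np.ones(3))
            assert dm.mixed_latent_response((1, 1, 1), (1, 1, 1), tau) == pytest.approx(1.0)

    def test_simplex_violation(self):
        with pytest.raises(ValueError, match="simplex"):
            dm.mixed_latent_response((1, 0, 0), (1, 1, 1), (0.5, 0.4, 0.4))


class TestResponseProbability:
    @pytest.mark.parametrize(
        "g, s, psi, expected",
        [(0.1, 0.1, 0.0, 0.1), (0.1, 0.1, 1.0, 0.9), (0.2, 0.3, 0.5, 0.45)],
    )
    def test_values(self, g, s, psi, expected):
        assert dm.response_probability(g, s, psi) == pytest.approx(expected)

    def test_monotonicity_violation(self):
        with pytest.raises(ValueError, match="monotonicity"):
            dm.response_probability(0.6, 0.5, 0.5)


class TestWorkedExample:
    """Correct-response probabilities of the four models for the example item."""

    TABLE = {  # profile -> (dina, dino, dinr, dinmix), 3 d.p.
        (0, 0, 0): (0.1, 0.1, 0.1, 0.1),
        (1, 0, 0): (0.1, 0.9, 0.367, 0.207),
        (0, 1, 0): (0.1, 0.9, 0.367, 0.207),
        (0, 0, 1): (0.1, 0.9, 0.367, 0.207),
        (1, 1, 0): (0.1, 0.9, 0.633, 0.233),
        (1, 0, 1): (0.1, 0.9, 0.633, 0.233),
        (0, 1, 1): (0.1, 0.9, 0.633, 0.233),
        (1, 1, 1): (0.9, 0.9, 0.9, 0.9),
    }

    @pytest.mark.parametrize("profile", PROFILES3)
    def test_all_four_columns(self, profile, table1_item, q111):
        dina, dino, dinr, dinmix_p = self.TABLE[profile]
        gs = dm.DinmixItemParams(0.1, 0.1)
        a = np.array(profile)
        psi_c = dm.latent_conjunctive(a, q111)
        psi_d = dm.latent_disjunctive(a, q111)
        psi_r = dm.latent_ratio(a, q111)
        assert round(dm.response_probability(0.1, 0.1, psi_c), 3) == dina
        assert round(dm.response_probability(0.1, 0.1, psi_d), 3) == dino
        assert round(dm.response_probability(0.1, 0.1, psi_r), 3) == dinr
        assert round(dm.dinmix_probability(table1_item, a, q111), 3) == dinmix_p


class TestSpecialCaseReduction:
    @pytest.mark.parametrize(
        "tau, rule",
        [((1, 0, 0), dm.latent_conjunctive),
         ((0, 1, 0), dm.latent_disjunctive),
         ((0, 0, 1), dm.latent_ratio)],
    )
    def test_degenerate_tau_recovers_pure_model(self, tau, rule):
        """tau at a simplex vertex reduces the mixture to its pure model for
        every profile and random (g, s)."""
        rng = np.random.default_rng(1)
        Q = dm.build_qmatrix(15, 5, "study1").entries
        for _ in range(5):
            g = rng.uniform(0.05, 0.4)
            s = rng.uniform(0.05, min(0.4, 0.95 - g))
            params = dm.DinmixItemParams(g, s, tau)
            for q_row in Q[5:]:
                for alpha in all_profiles(5):
                    mixed = dm.dinmix_probability(params, alpha, q_row)
                    pure = dm.response_probability(g, s, rule(alpha, q_row))
                    assert mixed == pytest.approx(pure)


class TestAdditive:
    def test_acdm_full_mastery(self):
        p = dm.AdditiveItemParams(0.1, (0.5, 0.3))
        assert dm.additive_probability(p, (1, 1), (1, 1)) == pytest.approx(0.9)

    def test_gdina_full_mastery(self):
        p = dm.AdditiveItemParams(
            0.1, (0.15, 0.1, 0.05), (0.05, 0.1, 0.15, 0.2)
        )
        assert dm.additive_probability(p, (1, 1, 1), (1, 1, 1)) == pytest.approx(0.9)

    def test_no_mastery_is_intercept(self):
        p = dm.AdditiveItemParams(0.1, (0.5, 0.3))
        assert dm.additive_probability(p, (0, 0), (1, 1)) == pytest.approx(0.1)

    def test_out_of_range_pattern_probability(self):
        with pytest.raises(ValueError, match="outside"):
            dm.AdditiveItemParams(0.5, (0.4, 0.4))

    def test_subset_ordering(self):
        assert required_subsets(3) == [(0, 1), (0, 2), (1, 2), (0, 1, 2)]


class TestPatternProbabilities:
    def test_worked_example_pattern_set(self, table1_item):
        pat = pattern_probabilities("dinmix", table1_item, (1, 1, 1))
        assert sorted(np.round(pat, 3)) == sorted(
            [0.1, 0.207, 0.207, 0.207, 0.233, 0.233, 0.233, 0.9]
        )

    def test_dina_pattern(self):
        pat = pattern_probabilities("dina", dm.DinmixItemParams(0.1, 0.1), (1, 1, 0))
        assert pat == pytest.approx([0.1, 0.1, 0.1, 0.9])

    @pytest.mark.parametrize("model", dm.MODELS)
    @pytest.mark.parametrize("q_row", [(1, 0, 0), (1, 1, 0), (1, 1, 1)])
    def test_matches_per_profile_calls(self, model, q_row):
        """Pattern vectors agree with brute-force per-profile evaluation for
        every model and every q-vector with up to three required attributes."""
        rng = np.random.default_rng(5)
        q = np.array(q_row)
        kstar = int(q.sum())
        if model in ("dina", "dino", "dinr", "dinmix"):
            params = dm.DinmixItemParams.for_item(
                0.12, 0.18, rng.dirichlet(np.ones(3)), q
            )
            prob = lambda a: dm.dinmix_probability(  # noqa: E731
                dm.DinmixItemParams(
                    params.g,
                    params.s,
                    {"dina": (1, 0, 0), "dino": (0, 1, 0), "dinr": (0, 0, 1)}.get(
                        model, params.tau
                    ),
                ),
                a,
                q,
            )
        elif model == "acdm":
            mains = rng.dirichlet(np.ones(kstar)) * 0.7
            params = dm.AdditiveItemParams(0.1, tuple(mains))
            prob = lambda a: dm.additive_probability(params, a, q)  # noqa: E731
        else:
            mains = rng.dirichlet(np.ones(kstar)) * 0.4
            n_int = len(required_subsets(kstar))
            inters = tuple(rng.dirichlet(np.ones(n_int)) * 0.3) if n_int else ()
            params = dm.AdditiveItemParams(0.1, tuple(mains), inters)
            prob = lambda a: dm.additive_probability(params, a, q)  # noqa: E731
        pat = pattern_probabilities(model, params, q)
        assert len(pat) == 2**kstar
        # reduced patterns enumerate required attributes, LSB first
        required = np.flatnonzero(q == 1)
        for r in range(2**kstar):
            alpha = np.zeros(3, dtype=int)
            for j, k in enumerate(required):
                alpha[k] = (r >> j) & 1
            assert pat[r] == pytest.approx(prob(alpha))


class TestInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.01, 0.45),
        s=st.floats(0.01, 0.45),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    def test_probability_bounds_and_corners(self, g, s, t1, t2):
        """Probabilities stay in [g, 1-s]; the all-zero profile hits g
        exactly and the all-ones profile 1-s exactly."""
        tau = np.array([t1, t2, max(1e-9, 2 - t1 - t2)])
        tau /= tau.sum()
        params = dm.DinmixItemParams(g, s, tuple(tau))
        q = np.array([1, 1, 1])
        pat = pattern_probabilities("dinmix", params, q)
        assert (pat >= g - 1e-12).all() and (pat <= 1 - s + 1e-12).all()
        assert pat[0] == pytest.approx(g)
        assert pat[-1] == pytest.approx(1 - s)

    def test_monotone_in_mastery(self):
        """Adding a mastered required attribute never lowers the probability."""
        rng = np.random.default_rng(2)
        q = np.array([1, 1, 1, 0, 1])
        params = dm.DinmixItemParams(0.1, 0.15, tuple(rng.dirichlet(np.ones(3))))
        for alpha in all_profiles(5):
            p0 = dm.dinmix_probability(params, alpha, q)
            for k in np.flatnonzero((q == 1) & (alpha == 0)):
                upgraded = alpha.copy()
                upgraded[k] = 1
                assert dm.dinmix_probability(params, upgraded, q) >= p0 - 1e-12

    def test_mix_is_convex_combination(self):
        rng = np.random.default_rng(3)
        q = np.array([1, 1, 1])
        tau = rng.dirichlet(np.ones(3))
        gs = dm.DinmixItemParams(0.1, 0.1)
        comp = np.stack(
            [
                pattern_probabilities(m, gs, q)
                for m in ("dina", "dino", "dinr")
            ]
        )
        mixed = pattern_probabilities(
            "dinmix", dm.DinmixItemParams(0.1, 0.1, tuple(tau)), q
        )
        assert mixed == pytest.approx(tau @ comp)


class TestLogLikelihood:
    def test_single_bernoulli(self):
        params = [dm.DinmixItemParams(0.5, 0.5 - 1e-9)]
        for y in (0, 1):
            ll = dm.log_likelihood(
                [[y]], [[1]], params, [[0]], "dina"
            )
            assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_worked_example_response(self, table1_item):
        ll = dm.log_likelihood(
            [[1]], [[1, 1, 1]], [table1_item], [[1, 0, 0]], "dinmix"
        )
        assert ll == pytest.approx(np.log(0.1 + 0.8 * (0.1 + 0.1 / 3)), abs=1e-9)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(11)
        Q = np.array([[1, 0], [0, 1], [1, 1], [1, 1], [0, 1]])
        params = [
            dm.DinmixItemParams.for_item(
                0.1 + 0.05 * i, 0.1, rng.dirichlet(np.ones(3)), Q[i]
            )
            for i in range(5)
        ]
        alphas = rng.integers(0, 2, size=(5, 2))
        Y = rng.integers(0, 2, size=(5, 5))
        expected = 0.0
        for n in range(5):
            for i in range(5):
                p = dm.dinmix_probability(params[i], alphas[n], Q[i])
                expected += np.log(p if Y[n, i] else 1 - p)
        got = dm.log_likelihood(Y, Q, params, alphas, "dinmix")
        assert got == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            dm.log_likelihood(
                np.ones((3, 2)), [[1], [1]], [None, None], np.ones((4, 1)), "dina"
            )


class TestTypes:
    def test_qmatrix_rejects_zero_row(self):
        with pytest.raises(ValueError, match="no attribute"):
            dm.QMatrix(np.array([[1, 0], [0, 0]]))

    def test_qmatrix_rejects_nonbinary(self):
        with pytest.raises(ValueError, match="binary"):
            dm.QMatrix(np.array([[1, 2]]))

    def test_unidimensional_tau_pinned(self):
        p = dm.DinmixItemParams.for_item(0.1, 0.1, (0.2, 0.3, 0.5), (0, 1, 0))
        assert p.tau == (1.0, 0.0, 0.0)

    def test_gs_constraints(self):
        with pytest.raises(ValueError):
            dm.DinmixItemParams(0.7, 0.4)
        with pytest.raises(ValueError):
            dm.DinmixItemParams(0.0, 0.1)
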