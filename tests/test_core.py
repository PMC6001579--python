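import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from femeta import (
    StudySummary,
    dersimonian_laird,
    inverse_variance_weights,
    optimal_affine_weights,
    pooled_estimate,
    validate_input,
)

from conftest import build_meta


class TestValidateInput:
    def test_symmetric_two_studies(self):
        meta = validate_input(
            [
                dict(study_id="a", estimate=0.0, se=1.0, n=100, variance_model="known"),
                dict(study_id="b", estimate=1.0, se=1.0, n=100, variance_model="known"),
            ]
        )
        assert meta.Phi == pytest.approx(2.0)
        assert meta.eta == pytest.approx([0.5, 0.5])
        assert meta.N == 200

    def test_derived_totals(self):
        meta = build_meta([0.0, 0.0], [1.0, 2.0], ns=[100, 300])
        assert meta.Phi == pytest.approx(1.25)
        assert meta.eta == pytest.approx([0.25, 0.75])

    def test_zero_se_rejected_naming_study(self):
        with pytest.raises(ValueError, match="bad_study"):
            StudySummary(study_id="bad_study", estimate=0.0, se=0.0, n=100)

    def test_single_study_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            validate_input(
                [dict(study_id="only", estimate=0.0, se=1.0, n=10,
                      variance_model="known")]
            )

    def test_welch_requires_group_fields(self):
        with pytest.raises(ValueError, match="group"):
            StudySummary(study_id="w", estimate=0.0, se=1.0, n=40,
                         variance_model="welch_normal")

    def test_df_resid_autofilled_for_pooled(self):
        s = StudySummary(study_id="p", estimate=0.0, se=1.0, n=40,
                         variance_model="pooled_normal")
        assert s.df_resid == 38

    def test_order_preserved(self):
        meta = build_meta([3.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert [s.estimate for s in meta.studies] == [3.0, 1.0, 2.0]


class TestInverseVarianceWeights:
    @pytest.mark.parametrize(
        "se, weights, variance",
        [
            ([1.0, 1.0], [0.5, 0.5], 0.5),
            ([1.0, 2.0], [0.8, 0.2], 0.8),
            ([1.0, 1.0, 1.0], [1 / 3, 1 / 3, 1 / 3], 1 / 3),
        ],
    )
    def test_examples(self, se, weights, variance):
        wv = inverse_variance_weights(se)
        assert wv.weights == pytest.approx(weights)
        assert wv.variance_of_combination == pytest.approx(variance)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inverse_variance_weights([])


class TestOptimalAffineWeights:
    @pytest.mark.parametrize(
        "cov, weights, variance",
        [
            (np.eye(2), [0.5, 0.5], 0.5),
            (np.diag([1.0, 4.0]), [0.8, 0.2], 0.8),
            ([[1.0, 0.5], [0.5, 1.0]], [0.5, 0.5], 0.75),
        ],
    )
    def test_examples(self, cov, weights, variance):
        wv = optimal_affine_weights(np.asarray(cov))
        assert wv.weights == pytest.approx(weights)
        assert wv.variance_of_combination == pytest.approx(variance)

    def test_singular_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            optimal_affine_weights(np.ones((2, 2)))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            optimal_affine_weights(np.array([[1.0, 0.2], [0.0, 1.0]]))

    def test_diagonal_matches_inverse_variance(self):
        rng = np.random.default_rng(7)
        se = rng.uniform(0.3, 3.0, size=5)
        wv_diag = optimal_affine_weights(np.diag(se**2))
        wv_iv = inverse_variance_weights(se)
        assert wv_diag.weights == pytest.approx(wv_iv.weights, abs=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_brute_force_minimization_oracle(self, k):
        """Closed-form weights match numerical minimization of v'Cv over
        affine v, and no other affine vector does better."""
        rng = np.random.default_rng(100 + k)
        a = rng.normal(size=(k, k))
        cov = a @ a.T + k * np.eye(k)
        wv = optimal_affine_weights(cov)

        def objective(free):
            v = np.append(free, 1.0 - free.sum())
            return v @ cov @ v

        res = optimize.minimize(objective, np.full(k - 1, 1.0 / k), method="BFGS")
        v_opt = np.append(res.x, 1.0 - res.x.sum())
        assert v_opt == pytest.approx(wv.weights, abs=1e-6)
        assert res.fun == pytest.approx(wv.variance_of_combination, rel=1e-8)
        for _ in range(50):
            v = rng.normal(size=k)
            v /= v.sum()
            assert v @ cov @ v >= wv.variance_of_combination - 1e-10


class TestPooledEstimate:
    def test_symmetric(self, symmetric_pair):
        res = pooled_estimate(symmetric_pair)
        assert res.estimate == pytest.approx(1.0)
        assert res.se == pytest.approx(1 / np.sqrt(2))

    def test_unequal(self, unequal_pair):
        res = pooled_estimate(unequal_pair)
        assert res.estimate == pytest.approx(1.4)
        assert res.se == pytest.approx(1 / np.sqrt(1.25))

    def test_flag_changes_tag_not_numbers(self, unequal_pair):
        naive = pooled_estimate(unequal_pair, assume_known_sigma=False)
        known = pooled_estimate(unequal_pair, assume_known_sigma=True)
        assert naive.method == "naive" and known.method == "known_sigma"
        assert naive.estimate == known.estimate and naive.ci == known.ci

    @given(c=st.floats(-5, 5), se=st.lists(st.floats(0.1, 5), min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_convexity(self, c, se):
        meta = build_meta(np.full(len(se), c), se)
        assert pooled_estimate(meta).estimate == pytest.approx(c)

    @given(shift=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=30)
    def test_location_equivariance(self, shift):
        base = build_meta([0.2, 1.4, -0.7], [0.5, 1.0, 2.0])
        moved = build_meta(np.array([0.2, 1.4, -0.7]) + shift, [0.5, 1.0, 2.0])
        r0, r1 = pooled_estimate(base), pooled_estimate(moved)
        assert r1.estimate == pytest.approx(r0.estimate + shift)
        assert r1.ci[0] == pytest.approx(r0.ci[0] + shift)
        assert r1.ci[1] == pytest.approx(r0.ci[1] + shift)

    def test_permutation_invariance(self):
        est, se = [0.2, 1.4, -0.7], [0.5, 1.0, 2.0]
        perm = [2, 0, 1]
        r0 = pooled_estimate(build_meta(est, se))
        r1 = pooled_estimate(
            build_meta([est[i] for i in perm], [se[i] for i in perm])
        )
        assert r1.estimate == pytest.approx(r0.estimate)
        assert r1.se == pytest.approx(r0.se)


class TestDerSimonianLaird:
    def test_homogeneous_truncates_to_pooled(self):
        meta = build_meta([1.0, 1.1, 0.9], [1.0, 1.0, 1.0])
        res = dersimonian_laird(meta)
        assert res.tau2_hat == 0.0
        assert res.mu_hat == pytest.approx(pooled_estimate(meta).estimate)

    def test_hand_evaluated_moment_formula(self, symmetric_pair):
        res = dersimonian_laird(symmetric_pair)
        # Q=2, k=2: tau2 = (2-1)/(2 - 2/2) = 1; equal weights keep mu at 1
        assert res.tau2_hat == pytest.approx(1.0)
        assert res.mu_hat == pytest.approx(1.0)

    @given(
        est=st.lists(st.floats(-3, 3), min_size=3, max_size=6),
        seed=st.integers(0, 10),
    )
    @settings(derandomize=True, max_examples=40)
    def test_tau2_nonnegative(self, est, seed):
        rng = np.random.default_rng(seed)
        se = rng.uniform(0.2, 2.0, size=len(est))
        assert dersimonian_laird(build_meta(est, se)).tau2_hat >= 0.0
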