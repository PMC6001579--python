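import numpy as np
import pytest

from femeta import (
    BootstrapDraws,
    boot_beta_interval,
    boot_zeta_interval,
    draw_bootstrap,
    empirical_quantile,
    pooled_estimate,
    q_statistic,
)

from conftest import build_meta


class TestDrawBootstrap:
    def test_seed_determinism(self, heterogeneous_six):
        d1 = draw_bootstrap(heterogeneous_six, 300, seed=9)
        d2 = draw_bootstrap(heterogeneous_six, 300, seed=9)
        for name in ("beta_star", "zeta2_star", "t_naive_star", "t_lssa_star"):
            assert np.array_equal(getattr(d1, name), getattr(d2, name))
        i1 = boot_beta_interval(d1, heterogeneous_six, method="boot_t_lssa")
        i2 = boot_beta_interval(d2, heterogeneous_six, method="boot_t_lssa")
        assert i1 == i2

    def test_b_one_rejected(self, heterogeneous_six):
        with pytest.raises(ValueError):
            draw_bootstrap(heterogeneous_six, 1, seed=0)

    def test_known_model_sampling_theory(self):
        """With known sigmas the replicate pooled estimates are unbiased for
        the original pooled estimate and E[zeta2*] = Q/Phi (fixed weights make
        Q* noncentral chi-square with noncentrality Q)."""
        meta = build_meta([0.3, 1.1, -0.6, 0.9], [0.4, 0.5, 0.6, 0.45])
        B = 4000
        d = draw_bootstrap(meta, B, seed=5)
        est = pooled_estimate(meta).estimate
        se_mc = d.beta_star.std(ddof=1) / np.sqrt(B)
        assert d.beta_star.mean() == pytest.approx(est, abs=3 * se_mc)
        q, _ = q_statistic(meta)
        z_mc = d.zeta2_star.std(ddof=1) / np.sqrt(B)
        assert d.zeta2_star.mean() == pytest.approx(q / meta.Phi, abs=3 * z_mc)

    def test_welch_model_draws(self):
        meta = build_meta([0.0, 1.0], [1.0, 1.0])  # placeholder; rebuilt below
        from femeta import StudySummary, validate_input

        studies = [
            StudySummary(study_id="w1", estimate=0.5, se=np.sqrt(2.0 / 20), n=40,
                         variance_model="welch_normal", group_n=(20, 20),
                         group_var=(1.0, 1.0)),
            StudySummary(study_id="w2", estimate=-0.5, se=np.sqrt(2.5 / 20), n=40,
                         variance_model="welch_normal", group_n=(20, 20),
                         group_var=(1.5, 1.0)),
        ]
        meta = validate_input(studies)
        d = draw_bootstrap(meta, 500, seed=3)
        assert np.all(np.isfinite(d.beta_star))
        assert np.all(np.isfinite(d.t_lssa_star))


class TestEmpiricalQuantile:
    @pytest.mark.parametrize("p", [0.025, 0.1, 0.5, 0.9, 0.975])
    def test_matches_inverse_ecdf_oracle(self, p):
        rng = np.random.default_rng(11)
        x = rng.normal(size=203)
        q = empirical_quantile(x, p)
        # smallest sample value whose ecdf reaches p
        xs = np.sort(x)
        ecdf = np.arange(1, x.size + 1) / x.size
        oracle = xs[np.argmax(ecdf >= p)]
        assert q == oracle

    def test_order_statistic_on_tiny_sample(self):
        x = np.array([3.0, 1.0, 2.0, 4.0])
        assert empirical_quantile(x, 0.5) == 2.0  # ceil(0.5*4) = 2nd order stat
        assert empirical_quantile(x, 0.51) == 3.0


class TestBetaIntervals:
    def test_unknown_method_rejected(self, heterogeneous_six):
        d = draw_bootstrap(heterogeneous_six, 50, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            boot_beta_interval(d, heterogeneous_six, method="bca")

    def test_degenerate_draws_zero_width(self, symmetric_pair):
        est = pooled_estimate(symmetric_pair).estimate
        const = np.full(100, est)
        d = BootstrapDraws(B=100, seed=0, beta_star=const,
                           zeta2_star=np.zeros(100),
                           t_naive_star=np.zeros(100),
                           t_lssa_star=np.zeros(100))
        for method in ("boot_percentile", "boot_t_naive", "boot_t_lssa"):
            lo, hi = boot_beta_interval(d, symmetric_pair, method=method).ci
            assert lo == pytest.approx(est) and hi == pytest.approx(est)

    def test_boot_normal_halfwidth_definition(self, heterogeneous_six):
        from scipy import stats

        d = draw_bootstrap(heterogeneous_six, 800, seed=2)
        res = boot_beta_interval(d, heterogeneous_six, method="boot_normal")
        z = stats.norm.ppf(0.975)
        sd = d.beta_star.std(ddof=1)
        assert (res.ci[1] - res.ci[0]) / 2 == pytest.approx(z * sd)
        assert res.estimate == pytest.approx(
            pooled_estimate(heterogeneous_six).estimate
        )

    def test_percentile_matches_naive_normal_under_known_sigma(self):
        """With known sigmas the replicate pooled estimate is exactly normal
        around the original one, so the percentile interval converges to the
        naive z-interval."""
        meta = build_meta([0.3, 1.1, -0.6], [0.4, 0.5, 0.6])
        d = draw_bootstrap(meta, 20000, seed=13)
        perc = boot_beta_interval(d, meta, method="boot_percentile").ci
        naive = pooled_estimate(meta).ci
        width = naive[1] - naive[0]
        assert perc[0] == pytest.approx(naive[0], abs=0.03 * width)
        assert perc[1] == pytest.approx(naive[1], abs=0.03 * width)


class TestZetaIntervals:
    def test_unknown_method_rejected(self, heterogeneous_six):
        d = draw_bootstrap(heterogeneous_six, 50, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            boot_zeta_interval(d, 1.0, method="boot_t_naive")

    def test_homogeneous_lower_endpoint_zero(self):
        meta = build_meta([1.0, 1.02, 0.98, 1.01], [0.5, 0.5, 0.5, 0.5],
                          model="pooled_normal")
        d = draw_bootstrap(meta, 400, seed=1)
        res = boot_zeta_interval(d, 0.0, method="boot_normal")
        assert res.ci[0] == 0.0

    def test_percentile_endpoints_are_order_statistics(self, heterogeneous_six):
        d = draw_bootstrap(heterogeneous_six, 321, seed=4)
        res = boot_zeta_interval(d, 1.0, level=0.9, method="boot_percentile")
        xs = np.sort(d.zeta2_star)
        lo = xs[int(np.ceil(0.05 * 321)) - 1]
        hi = xs[int(np.ceil(0.95 * 321)) - 1]
        assert res.ci == (max(0.0, lo), max(0.0, hi))

    def test_shift_monotonicity(self, heterogeneous_six):
        d = draw_bootstrap(heterogeneous_six, 200, seed=6)
        shifted = BootstrapDraws(
            B=d.B, seed=d.seed, beta_star=d.beta_star,
            zeta2_star=d.zeta2_star + 0.5,
            t_naive_star=d.t_naive_star, t_lssa_star=d.t_lssa_star,
        )
        r0 = boot_zeta_interval(d, 1.0, method="boot_percentile")
        r1 = boot_zeta_interval(shifted, 1.0, method="boot_percentile")
        assert r1.ci[0] >= r0.ci[0] and r1.ci[1] >= r0.ci[1]
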