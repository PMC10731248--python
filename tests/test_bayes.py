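"""Adaptive Metropolis-within-Gibbs sampler for the IVIM posterior."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ivimtools.model import AcquisitionScheme, IVIMParams, ivim_signal, rician_corrupt, RicianNoiseModel
from ivimtools.bayes import (
    McmcConfig,
    PosteriorChains,
    UnfittableVoxelError,
    adapt_step_lengths,
    fit_voxel_bayesian,
    run_mcmc,
    summarize_posterior,
)
from ivimtools.conventional import fit_voxel_free

# Non-overlapping d / d* ranges so the ordering constraint never binds and
# every marginal must be exactly uniform under the prior.
UNIFORM_TEST_BOUNDS = {
    "s0": (0.0, 2.0),
    "f": (0.0, 1.0),
    "d": (1e-6, 5e-3),
    "d_star": (5e-3, 0.5),
    "sigma": None,
}


class TestAdaptation:
    def test_step_update_rules(self):
        cfg = McmcConfig()
        steps = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        high = adapt_step_lengths(np.full(5, 0.9 * cfg.adapt_interval), steps, cfg)
        np.testing.assert_allclose(high, 1.5)
        low = adapt_step_lengths(np.full(5, 0.05 * cfg.adapt_interval), steps, cfg)
        np.testing.assert_allclose(low, 1 / 1.5)
        mid = adapt_step_lengths(np.full(5, 0.3 * cfg.adapt_interval), steps, cfg)
        np.testing.assert_allclose(mid, 1.0)

    def test_counts_out_of_range_rejected(self):
        cfg = McmcConfig()
        with pytest.raises(ValueError):
            adapt_step_lengths(np.full(5, cfg.adapt_interval + 1), np.ones(5), cfg)

    def test_schedule_defaults_match_protocol(self):
        cfg = McmcConfig()
        assert cfg.n_iterations == 20_000
        assert cfg.adapt_interval == 2_000
        cfg.validate()

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(burn_in=25_000).validate()
        with pytest.raises(ValueError):
            McmcConfig(burn_in=10_000, adapt_interval=3_000).validate()


class TestSummary:
    def _chains(self, arrays, cfg):
        n = len(next(iter(arrays.values())))
        samples = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
        return PosteriorChains(samples=samples, accept_counts=np.zeros((1, 5)),
                               step_lengths=np.ones((2, 5)), config=cfg)

    def test_constant_chain_gives_zero_width_interval(self):
        cfg = McmcConfig(n_iterations=100, burn_in=50, adapt_interval=50)
        ch = self._chains({k: np.full(100, 0.2 if k == "f" else 1.0)
                           for k in ("s0", "f", "d", "d_star", "sigma")}, cfg)
        p, ci = summarize_posterior(ch, cfg)
        assert p.f == pytest.approx(0.2, rel=1e-12)
        assert ci["f"] == (pytest.approx(0.2), pytest.approx(0.2))
        assert "DEGENERATE" in p.flags  # frozen chain is flagged

    def test_order_statistics_convention(self):
        cfg = McmcConfig(n_iterations=201, burn_in=100, adapt_interval=100)
        vals = np.concatenate([np.zeros(100), np.arange(1.0, 102.0)])
        arrays = {k: vals if k == "f" else np.full(201, 1.0)
                  for k in ("s0", "f", "d", "d_star", "sigma")}
        p, ci = summarize_posterior(self._chains(arrays, cfg), cfg,
                                    point_estimate="median")
        assert p.f == 51.0
        assert ci["f"] == (pytest.approx(3.5), pytest.approx(98.5))

    def test_single_sample_summary_warns(self, caplog):
        cfg = McmcConfig(n_iterations=101, burn_in=100, adapt_interval=100)
        arrays = {k: np.linspace(0.1, 0.2, 101) for k in ("s0", "f", "d", "d_star", "sigma")}
        import logging
        with caplog.at_level(logging.WARNING):
            p, ci = summarize_posterior(self._chains(arrays, cfg), cfg)
        assert ci["f"][0] == ci["f"][1]
        assert any("single retained sample" in r.message for r in caplog.records)


class TestSampler:
    def test_same_seed_bit_identical(self, scheme, clean_table2_signal):
        noisy = rician_corrupt(clean_table2_signal, RicianNoiseModel(0.02), 5)
        cfg = McmcConfig(n_iterations=4000, burn_in=2000, adapt_interval=500, seed=11)
        a = run_mcmc(noisy, scheme, cfg)
        b = run_mcmc(noisy, scheme, cfg)
        for name in a.samples:
            np.testing.assert_array_equal(a.samples[name], b.samples[name])

    def test_noise_free_posterior_concentrates(self, scheme):
        truth = IVIMParams(1.0, 0.15, 1.0e-3, 50e-3)
        clean = ivim_signal(truth, scheme)
        cfg = McmcConfig(seed=2, estimate_sigma=False, sigma=1e-4)
        p, _ = summarize_posterior(run_mcmc(clean, scheme, cfg), cfg,
                                   point_estimate="median")
        assert abs(p.f - truth.f) / truth.f < 0.02
        assert abs(p.d - truth.d) / truth.d < 0.02
        assert abs(p.d_star - truth.d_star) / truth.d_star < 0.10

    def test_noise_free_agrees_with_free_fit(self, scheme):
        truth = IVIMParams(1.0, 0.12, 1.1e-3, 20e-3)
        clean = ivim_signal(truth, scheme)
        free = fit_voxel_free(clean, scheme)
        cfg = McmcConfig(seed=3, estimate_sigma=False, sigma=1e-4)
        bay = fit_voxel_bayesian(clean, scheme, cfg)
        for a, b in ((bay.s0, free.s0), (bay.f, free.f), (bay.d, free.d),
                     (bay.d_star, free.d_star)):
            assert abs(a - b) / abs(b) < 0.01

    def test_prior_only_marginals_uniform(self, scheme):
        cfg = McmcConfig(n_iterations=30_000, burn_in=10_000, adapt_interval=2_000,
                         seed=4, prior_only=True, prior_bounds=dict(UNIFORM_TEST_BOUNDS))
        ch = run_mcmc(np.full(10, 0.5), scheme, cfg)
        for name, (lo, hi) in (("s0", (0, 2)), ("f", (0, 1)),
                               ("d", (1e-6, 5e-3)), ("d_star", (5e-3, 0.5))):
            x = ch.post_burn_in(name)[::25]
            h, _ = np.histogram(x, bins=8, range=(lo, hi))
            assert chisquare(h).pvalue > 0.01, name

    def test_samples_respect_support_and_ordering(self, scheme, clean_table2_signal):
        noisy = rician_corrupt(clean_table2_signal, RicianNoiseModel(0.03), 9)
        cfg = McmcConfig(n_iterations=4000, burn_in=2000, adapt_interval=500, seed=12)
        ch = run_mcmc(noisy, scheme, cfg)
        lo, hi = cfg.resolve_bounds(noisy)
        for j, name in enumerate(("s0", "f", "d", "d_star", "sigma")):
            assert np.all(ch.samples[name] >= lo[j] - 1e-15)
            assert np.all(ch.samples[name] <= hi[j] + 1e-15)
        assert np.all(ch.samples["d_star"] >= ch.samples["d"])

    def test_scale_equivariance_of_dimensionless_marginals(self, scheme, clean_table2_signal):
        noisy = rician_corrupt(clean_table2_signal, RicianNoiseModel(0.02), 21)
        cfg = McmcConfig(n_iterations=4000, burn_in=2000, adapt_interval=500, seed=33)
        a = run_mcmc(noisy, scheme, cfg)
        b = run_mcmc(noisy * 2.0, scheme, cfg)
        # equal up to float rounding of the rescaled chain initialisation
        for name in ("f", "d", "d_star"):
            np.testing.assert_allclose(a.samples[name], b.samples[name], rtol=1e-6)
        np.testing.assert_allclose(2.0 * a.samples["s0"], b.samples["s0"], rtol=1e-6)

    def test_chain_length_stability(self, scheme, clean_table2_signal):
        noisy = rician_corrupt(clean_table2_signal, RicianNoiseModel(0.02), 17)
        cfg20 = McmcConfig(seed=8)
        cfg40 = McmcConfig(n_iterations=40_000, burn_in=20_000, adapt_interval=2_000, seed=8)
        p20, _ = summarize_posterior(run_mcmc(noisy, scheme, cfg20), cfg20)
        ch40 = run_mcmc(noisy, scheme, cfg40)
        p40, _ = summarize_posterior(ch40, cfg40)
        for name, v20, v40 in (("f", p20.f, p40.f), ("d", p20.d, p40.d),
                               ("d_star", p20.d_star, p40.d_star)):
            post = ch40.post_burn_in(name)
            iqr = np.percentile(post, 75) - np.percentile(post, 25)
            assert abs(v20 - v40) < iqr, name

    def test_f_zero_truth_leaves_dstar_wide(self, scheme):
        truth = IVIMParams(1.0, 0.0, 1.0e-3, 10e-3)
        clean = ivim_signal(truth, scheme)
        cfg = McmcConfig(seed=6, estimate_sigma=False, sigma=1e-4)
        ch = run_mcmc(clean, scheme, cfg)
        p, ci = summarize_posterior(ch, cfg)
        assert p.f < 0.03
        assert abs(p.d - truth.d) / truth.d < 0.02
        lo, hi = cfg.resolve_bounds(clean)
        # D* carries no information at f=0: the 95% interval spans most of the prior
        assert (ci["d_star"][1] - ci["d_star"][0]) > 0.4 * (hi[3] - lo[3])

    def test_unfittable_voxels_raise(self, scheme):
        with pytest.raises(UnfittableVoxelError):
            run_mcmc(np.zeros(10), scheme)
        with pytest.raises(ValueError):
            run_mcmc(np.ones(3), AcquisitionScheme(b_values=(0, 250, 1000)))
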