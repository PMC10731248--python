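"""Fit one noisy voxel with all four analysis arms.

Compares full nonlinear least squares, the two segmented variants, and the
Bayesian posterior (with 95% credible intervals).  At SNR 50 the perfusion
fraction is only weakly identified, which is why the Bayesian estimate with
its physiological prior is typically closest to the truth.
"""

import numpy as np

from ivimtools import (
    AcquisitionScheme, IVIMParams, McmcConfig, RicianNoiseModel,
    SegmentedConfig, fit_voxel_free, fit_voxel_segmented,
    ivim_signal, rician_corrupt, run_mcmc, summarize_posterior,
)

scheme = AcquisitionScheme()
truth = IVIMParams(s0=1.0, f=0.1081, d=0.95e-3, d_star=6.20e-3)
noisy = rician_corrupt(ivim_signal(truth, scheme), RicianNoiseModel(1 / 50), rng=4)


def row(name, p):
    f_pct, d_r, ds_r = p.to_reporting_units()
    print(f"{name:25s} f={f_pct:6.2f}%  D={d_r:5.3f}  D*={ds_r:6.2f}  (x1e-3 mm^2/s)")


row("truth", truth)
row("free NLLS", fit_voxel_free(noisy, scheme))
row("segmented-unconstrained", fit_voxel_segmented(noisy, scheme))
row("segmented-constrained", fit_voxel_segmented(noisy, scheme, SegmentedConfig(constrained=True)))

cfg = McmcConfig(seed=4)
chains = run_mcmc(noisy, scheme, cfg)
bayes, ci = summarize_posterior(chains, cfg)
row("Bayesian posterior mean", bayes)
print(f"{'':25s} 95% CI for f: [{100 * ci['f'][0]:.2f}%, {100 * ci['f'][1]:.2f}%]")
print()
print("The least-squares arms scatter widely on single voxels; the Bayesian")
print("estimate shrinks toward physiologically plausible values and reports")
print("its own uncertainty.")
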