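"""Simulate a tumour phantom and push it through the map-fitting pipeline.

Generates an ellipsoidal lesion with known IVIM truth, fits parametric maps
inside the ROI with the free and Bayesian arms, and compares the within-ROI
medians against the generating values — the same baseline markers the
two-timepoint analysis is built on.
"""

from ivimtools import McmcConfig, fit_map, roi_median
from ivimtools.synthetic import PhantomSpec, generate_phantom

spec = PhantomSpec(seed=7, snr=50.0)  # default: 16x16x4 grid, f=10.81%, D=0.95, D*=6.20
dwi, mask, truth_maps = generate_phantom(spec)
print(f"phantom: {mask.n_voxels} lesion voxels at SNR {spec.snr:.0f}")

free_maps = fit_map(dwi, mask, method="free")
free = roi_median(free_maps, mask)
print(f"free fit   ROI medians: f={free.f_median:6.2f}%  D={free.d_median:.3f}  "
      f"D*={free.dstar_median:6.2f}")

bayes_maps = fit_map(dwi, mask, method="bayesian", mcmc_config=McmcConfig(seed=7))
bay = roi_median(bayes_maps, mask)
print(f"bayesian   ROI medians: f={bay.f_median:6.2f}%  D={bay.d_median:.3f}  "
      f"D*={bay.dstar_median:6.2f}")
print(f"truth                 : f= 10.81%  D=0.950  D*=  6.20")
print()
print("Least-squares f is biased upward at this SNR; the Bayesian median sits")
print("close to the generating truth — the motivation for the Bayesian arm.")
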