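# ivimtools

Bayesian and least-squares analysis of intravoxel incoherent motion (IVIM)
diffusion-weighted MRI, aimed at longitudinal tumour-response studies: from
4D DWI volumes and a tumour mask to voxelwise parametric maps, within-ROI
medians, percentage-change markers, and responder-group statistics — plus a
synthetic phantom/cohort generator so the whole pipeline runs and is tested
without any patient data.

## The model

The voxel signal at diffusion weighting *b* is the biexponential IVIM form

```
S(b) = S0 · [ f · exp(−b·D*) + (1 − f) · exp(−b·D) ]
```

where *f* is the perfusion fraction (capillary blood signal volume), *D* the
tissue diffusion coefficient, and *D\** the pseudodiffusion coefficient of
blood moving through randomly oriented capillaries.  Magnitude MR noise is
Rician, `p(m | ν, σ) = (m/σ²)·exp(−(m²+ν²)/2σ²)·I₀(mν/σ²)`, and no
noise-floor correction is applied anywhere — the Rician likelihood is used
exactly.

Four analysis arms estimate `(S0, f, D, D*)` per voxel:

* **bayesian** — adaptive Metropolis-within-Gibbs MCMC on the joint
  posterior (Rician likelihood × uniform prior over physiological ranges,
  noise scale σ marginalised), 20,000 sweeps with step-length adaptation
  every 2,000 during the first half; point estimate = marginal posterior
  mean, 95% credible intervals from chain percentiles.
* **free** — box-constrained nonlinear least squares over all four
  parameters, multi-started.
* **segmented_unconstrained / segmented_constrained** — the classic
  two-stage fits: *D* from the log-linear high-b tail (b ≥ 250 s/mm²),
  then either `(S0, f, D*)` re-fit, or *f* pinned to the intercept formula
  `1 − A/m(0)` with only *D\** fit.

Downstream, tumour-ROI medians of *f*, *D*, *D\** at two timepoints give the
percentage-change markers `[Cycle1 − Baseline]/Baseline × 100`, compared
between good and poor responders (Miller–Payne grades 4–5 vs 1–3) with
Wilcoxon rank-sum tests and correlated against the Ki-67 proliferation
change with Spearman's rho.

## Worked example

```
$ python examples/03_phantom_to_maps.py
phantom: 136 lesion voxels at SNR 50
free fit   ROI medians: f= 11.83%  D=0.945  D*=  5.92
bayesian   ROI medians: f= 10.03%  D=0.987  D*= 15.90
truth                 : f= 10.81%  D=0.950  D*=  6.20
```

An ellipsoidal lesion is simulated with the cohort-median truth
(f = 10.81 %, D = 0.95, D\* = 6.20 ×10⁻³ mm²/s) at SNR 50 and fitted inside
the mask.  The free-fit ROI median of *f* overshoots (the perfusion
fraction is weakly identified voxel-by-voxel and least squares has no
regularisation), while the Bayesian median lands close to the truth — the
reason the Bayesian arm is the primary estimator.  `D` is tightly estimated
by both; single-voxel `D*` stays the noisiest parameter.

The other examples show the forward model (`01`), all four arms on one
voxel with credible intervals (`02`), and a full synthetic-cohort analysis
with the grouped report (`04`).

A thin CLI wraps the same library calls:

```
ivimtools simulate --kind phantom --out work --seed 7
ivimtools fit --dwi work/dwi.nii --bval work/dwi.bval --mask work/mask.nii \
              --method bayesian --seed 7 --out work/maps
ivimtools summarize --maps-dir work/maps --method bayesian \
              --mask work/mask.nii --out work/roi.csv
ivimtools analyze --cohort cohort.csv --out report.csv
ivimtools run-all --out work --seed 7
```

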