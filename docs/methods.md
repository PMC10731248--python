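# Methods

## Signal model and units

A voxel's diffusion-weighted magnitude signal is modelled as the
biexponential IVIM form

S(b) = S0 · [ f·exp(−b·D\*) + (1−f)·exp(−b·D) ],

with the default acquisition of ten b-values {0, 30, 60, 90, 120, 250, 400,
600, 800, 1000} s/mm² (three orthogonal gradient directions averaged
upstream; gradient timing δ/Δ = 13.1/25.4 ms, TE 50 ms, TR 2400 ms are
carried as metadata only).  Internally D and D\* are in mm²/s and f is a
fraction; the conventional reporting units (f in %, D and D\* in ×10⁻³
mm²/s) are applied only at the map/ROI reporting boundary, so no 1000×
factors can leak into the fitting.

Magnitude noise is Rician.  The log-density is evaluated with the
exponentially scaled Bessel function `i0e` (no overflow at high SNR), and
the forward simulator draws `m = |(s + g₁σ) + i g₂σ|`.  No noise-floor
(bias) correction is applied anywhere: the likelihood models the magnitude
distribution exactly, and the same convention is used at both timepoints.

## Bayesian estimator

The joint posterior over (S0, f, D, D\*, σ) combines the Rician likelihood
with a uniform joint prior.  One MCMC sweep updates each parameter in turn
by a Metropolis–Hastings step (componentwise Gibbs-style scan); proposals
are Gaussian random walks on transformed coordinates — S0 on its natural
scale, f on the logit scale, D, D\* and σ on the log scale — with the
transform Jacobians folded into the target density so the *natural-scale*
prior stays uniform.  The schedule is 20,000 total sweeps; step lengths
adapt every 2,000 sweeps during the first 10,000 (×1.5 above a 0.2–0.5
acceptance band, ÷1.5 below it) and are frozen afterwards, so retained
samples come from a fixed kernel.  Chains start from the
segmented-unconstrained fit (mid-range fallback), with σ initialised from
its residuals.  Proposals outside the prior box, or violating the ordering
constraint D\* ≥ D that resolves the f ↔ 1−f label-switching symmetry, are
rejected.

**Prior ranges.**  f ∈ [0, 0.4], D ∈ [0.2, 2.5]×10⁻³ mm²/s,
D\* ∈ [1, 50]×10⁻³ mm²/s, S0 ∈ [0, 2·max(signal)], and σ ∈
[10⁻⁵, 0.5]·max(signal) with a 1/σ (log-flat) prior.  These are deliberate
physiological choices, not mathematical maxima: free water at body
temperature diffuses at ~3×10⁻³ mm²/s and tumour ROIs exclude cystic and
necrotic areas, breast-lesion perfusion fractions above ~40 % are not
observed, and reported tumour pseudodiffusion sits well below 50×10⁻³
mm²/s.  The biexponential is weakly identified at clinical SNR — the
Cramér–Rao bound for an *unbiased* f estimator at the cohort-median
parameters and SNR 50 is σ(f) ≈ 0.13 — so this prior information is what
regularises the voxelwise estimates; grid-integration experiments show that
priors extended to "safe" mathematical ranges (for instance D\* up to
0.5 mm²/s) place most prior mass on implausible fast-compartment
explanations and roughly double the f recovery error even with perfect
sampling.

**Point estimate and intervals.**  The default point estimate is the
marginal posterior mean; for the skewed, bounded f and D\* marginals it is
distinctly more accurate than the marginal median (recovery experiments at
SNR 50 give median-|error| ≈ 0.025 for the mean vs ≈ 0.046 for the median
under identical chains), and it is the standard choice in Bayesian IVIM.
The marginal median is available as an option.  95 % credible intervals are
the empirical 2.5/97.5 percentiles of the post-burn-in chain.  Their
calibration is validated by the Bayesian self-consistency check: with voxel
truths drawn from the prior, the 95 % interval for f covers the truth at
its nominal rate (the test band 90–99 % allows binomial error at 200
voxels).  At a single fixed truth the coverage of credible intervals is not
nominal — with weak identifiability it approaches 100 % — which is a
property of credible intervals, not a defect.

Voxels are fit independently; no spatial coupling between neighbouring
voxels is implemented.

## Conventional estimators

*Free*: box-constrained nonlinear least squares over all four parameters,
parametrised as D\* = D + δ (δ ≥ 0) so the ordering constraint holds by
construction; three starts (segmented estimate, a perturbed copy, a generic
mid-range point), best residual wins with ties broken by the lowest D\*.
When D\* collapses onto D the compartments are a single exponential and f
is arbitrary along a flat cost valley; the fit is then reported in the
canonical monoexponential form (f = 0) and flagged unidentifiable.
Conventional-arm bounds stay at the generous ranges f ∈ [0,1],
D ∈ [0, 5]×10⁻³, D\* ∈ [0, 0.5] mm²/s — these arms are the unregularised
comparators.

*Segmented*: stage 1 fits ln m(b) = ln A − b·D by weighted least squares on
b ≥ 250 s/mm² with weights m(b)² (the Gauss–Markov weighting for
log-transformed noise); the threshold 250 is the smallest acquired b at or
above the conventional ~200 s/mm² perfusion cut-off.  Stage 2 either re-fits
(S0, f, D\*) with D fixed (unconstrained), or pins S0 = m(0) and
f = 1 − A/m(0), clamped to [0, 1], and fits D\* alone (constrained).  The
stage-1 D estimate is always retained; its upward bias when D\* is slow
(e.g. e^(−250·0.006) ≈ 0.22 still contaminating the tail) is documented by a
test against the closed-form weighted fit on the exact biexponential.

Estimates landing on a bound are kept but flagged; invalid voxels are
excluded from ROI medians with their count logged.

## ROI pipeline and clinical markers

Per-direction 5D acquisitions are averaged arithmetically over the
direction axis.  Maps are fit only inside the tumour mask (whole-volume
MCMC would be wasteful; all reported statistics are within-tumour), with
NaN sentinels outside and per-voxel validity tracked.  ROI summaries are
medians over valid masked voxels (all slices pooled; midpoint convention at
even counts).  Longitudinal markers are
[Cycle1 − Baseline]/Baseline × 100 % per parameter, and
[Ki-67 at excision − Ki-67 at biopsy]/biopsy × 100 % for histology.
Masks must already be on the DWI grid with a matching affine — mismatches
are hard errors, and only a nearest-neighbour convenience resampler is
provided.

## Cohort statistics

Miller–Payne grades 4–5 define good responders (≥ 90 % cellularity
reduction), 1–3 poor.  Group comparisons use the two-sided Wilcoxon
rank-sum test: exact by full enumeration for tie-free samples up to
n₁+n₂ = 25 (covering the 7-vs-9 cohort comparison), otherwise the normal
approximation with tie and continuity corrections.  Associations use
Spearman's rho (product-moment correlation of midranks) with an exact
permutation p-value for n ≤ 9 and the t approximation beyond.
Shapiro–Wilk normality results are computed and reported but never gate
which test runs — the battery is nonparametric throughout.  Raw p-values
are reported at α = 0.05 with the number of tests annotated; no
multiple-testing correction is applied.  Median/IQR reporting uses linear
interpolation between order statistics (R default type 7) everywhere.
Patients missing the Cycle-1 scan are excluded listwise from %change
analyses only and retained at baseline.

## Synthetic data

**Phantoms** place an ellipsoidal lesion with homogeneous (optionally
field-valued) IVIM truth in a 3D grid; background true signal is zero, so
background magnitudes are pure Rayleigh noise.  SNR is defined as S0/σ with
a default of 50, representative of clinical breast DWI at b = 0.

**Cohorts** default to the study conditions: 8 good / 9 poor responders at
baseline, one good responder missing the Cycle-1 scan (7/9 at follow-up).
Baseline ROI medians are log-normal around (f, D, D\*) = (10.81 %, 0.95,
6.20 ×10⁻³ mm²/s) with log-sd set so the generated IQRs match the published
interquartile ranges to first order (σ = ln(q₃/q₁)/2z₀.₇₅); percentage
changes are normal with group medians (f: −7.98 good / +10.04 poor;
D: +28.87 / +15.54; D\*: −16.12 / −14.89) and spreads derived the same way
from the group IQRs.  The Ki-67 marker is generated through its "survival
ratio" w = 100·excision/biopsy, log-normal at cohort level (median 35,
log-sd 0.9, bracketing the published exemplar changes of −95 % and −48 %),
with biopsy values uniform on [10, 40] %.  The w draw is rank-coupled to
the patient's %change(f) through a Gaussian copula at cohort level: the
%change(f) value is mapped through the pooled two-group mixture CDF to a
normal score, and the latent correlation is the exact inversion of the
finite-sample moment E[r_s] = 6/(π(n+1))·((n−2)·asin(r/2) + asin r), so the
*sample* Spearman coefficient at the follow-up size is centred on the
requested coupling (default 0.59).  Setting the coupling to zero makes the
markers independent.  `scripts/calibrate_generator.py` verifies this
mapping by Monte Carlo.

With voxel fidelity the generator additionally emits one phantom per
patient-visit whose homogeneous lesion truth equals that visit's drawn
medians, so the full fit → median → %change → statistics chain can be
exercised end to end.

What the generator does **not** emulate: intra-tumour heterogeneity beyond
optional smooth truth fields, partial-volume and registration effects, EPI
distortion or motion, inter-scan drift, and any anatomical realism.
Passing tests therefore demonstrate correctness of the estimators and
statistics under the stated noise model and effect sizes — not robustness
to those real-world artefacts.

## Problem sizes and numerics

Recovery and calibration experiments use 100 voxels (SNR 50) and 200
voxels (SNR 30) with the default 20,000-sweep chains; cohort-level checks
average 200 generated cohorts.  Optimiser tolerances are 10⁻¹⁴ (xtol/ftol/
gtol) for the least-squares arms; chain determinism is per-voxel, with map
fits deriving each voxel's seed from the configured seed and the voxel's
flat index.  Degenerate inputs (all-zero signal, non-positive magnitudes,
constant signals) are flagged or rejected rather than fitted silently.

## Known limitations

Single-voxel D\* remains noisy at clinical SNR even for the Bayesian arm;
the posterior-mean estimator trades a small boundary bias near f = 0 for a
large variance reduction elsewhere; the componentwise random-walk sampler
has autocorrelation times of order 10²  sweeps on the correlated (f, D\*)
ridge, so summaries from the default schedule carry Monte-Carlo error of a
few percent of the posterior spread; and the cohort generator's dispersions
beyond the published IQRs are first-order calibrations, not estimates of
any real population.
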