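"""Compiled per-voxel Metropolis-within-Gibbs kernel.

The sampler state is kept in transformed coordinates — s0 on its natural
scale, f on the logit scale, d / d* / sigma on the log scale — with the
Jacobian of each transform folded into the log-posterior so that the
stationary distribution on the *natural* scale is the uniform joint prior
times the Rician likelihood.  The noise scale sigma carries a 1/sigma prior
on a bounded range, i.e. a flat density in log sigma (no Jacobian term).

Parameter order everywhere: [s0, f, d, d_star, sigma].
"""

import math

import numpy as np
from numba import njit

N_PARAMS = 5


@njit(cache=False)
def _log_i0(x: float) -> float:
    """log of the modified Bessel function I0, polynomial approximation.

    Abramowitz & Stegun 9.8.1 (|x| <= 3.75) and 9.8.2 (x > 3.75); absolute
    error below 2e-7 in the polynomial, which is negligible against the
    likelihood scales involved.
    """
    ax = abs(x)
    if ax <= 3.75:
        t = x / 3.75
        t2 = t * t
        val = (1.0 + t2 * (3.5156229 + t2 * (3.0899424 + t2 * (1.2067492
               + t2 * (0.2659732 + t2 * (0.0360768 + t2 * 0.0045813))))))
        return math.log(val)
    t = 3.75 / ax
    poly = (0.39894228 + t * (0.01328592 + t * (0.00225319 + t * (-0.00157565
            + t * (0.00916281 + t * (-0.02057706 + t * (0.02635537
            + t * (-0.01647633 + t * 0.00392377))))))))
    return ax - 0.5 * math.log(ax) + math.log(poly)


@njit(cache=False)
def _log_posterior(x, signal, b, lo, hi, likelihood_on):
    """Log-posterior in transformed coordinates x = [s0, logit f, log d, log d*, log sigma]."""
    s0 = x[0]
    f = 1.0 / (1.0 + math.exp(-x[1]))
    d = math.exp(x[2])
    ds = math.exp(x[3])
    sig = math.exp(x[4])
    if s0 < lo[0] or s0 > hi[0]:
        return -np.inf
    if f < lo[1] or f > hi[1]:
        return -np.inf
    if d < lo[2] or d > hi[2]:
        return -np.inf
    if ds < lo[3] or ds > hi[3]:
        return -np.inf
    if sig < lo[4] or sig > hi[4]:
        return -np.inf
    if ds < d:  # ordering constraint resolves the f <-> 1-f degeneracy
        return -np.inf
    # Jacobians of the logit/log transforms (flat natural-scale prior);
    # sigma has prior 1/sigma, flat in log sigma, so no term.
    lp = math.log(f * (1.0 - f)) + x[2] + x[3]
    if likelihood_on:
        s2 = sig * sig
        for i in range(b.shape[0]):
            nu = s0 * (f * math.exp(-b[i] * ds) + (1.0 - f) * math.exp(-b[i] * d))
            m = signal[i]
            z = m * nu / s2
            lp += math.log(m / s2) - (m * m + nu * nu) / (2.0 * s2) + _log_i0(z)
    return lp


@njit(cache=False)
def run_chain(
    signal,
    b,
    n_iter,
    adapt_interval,
    burn_in,
    lo,
    hi,
    init_transformed,
    steps_init,
    target_low,
    target_high,
    estimate_sigma,
    likelihood_on,
    seed,
):
    """Run one adaptive Metropolis-within-Gibbs chain.

    One sweep updates each parameter in turn with a Gaussian random-walk
    proposal in the transformed coordinate, accepted or rejected against the
    Rician log-posterior.  Step lengths adapt every ``adapt_interval`` sweeps
    during the first ``burn_in`` sweeps only (x1.5 when the window acceptance
    rate exceeds ``target_high``, /1.5 below ``target_low``), then stay
    frozen so retained samples come from a fixed kernel.

    Returns (samples, accept_counts, step_history) where ``samples`` is
    (n_iter, 5) on the natural scale, ``accept_counts`` is (n_windows, 5)
    per-window acceptance tallies and ``step_history`` is (n_windows + 1, 5).
    """
    np.random.seed(seed)
    n_windows = (n_iter + adapt_interval - 1) // adapt_interval
    samples = np.empty((n_iter, N_PARAMS))
    accept = np.zeros((n_windows, N_PARAMS), dtype=np.int64)
    steps = steps_init.copy()
    step_hist = np.empty((n_windows + 1, N_PARAMS))
    step_hist[0] = steps

    x = init_transformed.copy()
    lp = _log_posterior(x, signal, b, lo, hi, likelihood_on)
    for it in range(n_iter):
        w = it // adapt_interval
        for j in range(N_PARAMS):
            if j == 4 and not estimate_sigma:
                continue
            old = x[j]
            x[j] = old + steps[j] * np.random.normal()
            lp_new = _log_posterior(x, signal, b, lo, hi, likelihood_on)
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                accept[w, j] += 1
            else:
                x[j] = old
        samples[it, 0] = x[0]
        samples[it, 1] = 1.0 / (1.0 + math.exp(-x[1]))
        samples[it, 2] = math.exp(x[2])
        samples[it, 3] = math.exp(x[3])
        samples[it, 4] = math.exp(x[4])
        if (it + 1) % adapt_interval == 0:
            if (it + 1) <= burn_in:
                for j in range(N_PARAMS):
                    if j == 4 and not estimate_sigma:
                        continue
                    rate = accept[w, j] / adapt_interval
                    if rate > target_high:
                        steps[j] *= 1.5
                    elif rate < target_low:
                        steps[j] /= 1.5
            step_hist[w + 1] = steps
    if n_iter % adapt_interval != 0:
        step_hist[n_windows] = steps
    return samples, accept, step_hist
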