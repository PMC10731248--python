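"""Least-squares IVIM estimators: free (full) and segmented fitting.

Three conventional algorithms are provided as comparison arms to the Bayesian
estimator:

* ``free`` — box-constrained nonlinear least squares over all four
  parameters simultaneously, multi-started because the 4-parameter
  biexponential objective is multimodal.
* ``segmented_unconstrained`` (SU) — a two-stage fit: the tissue diffusion
  coefficient D is first estimated from the high-b monoexponential tail,
  then (S0, f, D*) are re-fit over all b with D fixed.
* ``segmented_constrained`` (SC) — same stage 1, but S0 is pinned to the
  measured b=0 signal and f to the intercept formula ``1 - A / m(0)``, so
  stage 2 fits D* alone.

The ordering constraint D* >= D is enforced in all arms (pseudodiffusion is
biologically faster than tissue diffusion), which also removes the f <-> 1-f
label-switching degeneracy of the symmetric biexponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model import (
    AT_BOUND,
    DEGENERATE,
    F_UNIDENTIFIABLE,
    NO_CONVERGENCE,
    STAGE1_FAILURE,
    AcquisitionScheme,
    IVIMParams,
)

__all__ = ["SegmentedConfig", "default_bounds", "fit_voxel_free", "fit_voxel_segmented"]

# Threshold below which a fitted perfusion fraction is treated as absent,
# leaving D* uninformed by the data.
_F_TINY = 1e-3


def default_bounds(signal: np.ndarray) -> Dict[str, Tuple[float, float]]:
    """Box constraints shared by all estimators, generous physiological ranges.

    d and d_star in mm^2/s; s0 upper bound scales with the data so estimates
    are equivariant under rescaling of the signal.
    """
    smax = float(np.max(signal))
    return {
        "s0": (0.0, 2.0 * smax),
        "f": (0.0, 1.0),
        "d": (0.0, 5e-3),
        "d_star": (0.0, 0.5),
    }


@dataclass
class SegmentedConfig:
    """Configuration of the two-stage (segmented) fits.

    ``b_threshold`` is the smallest b-value (s/mm^2) included in the
    monoexponential stage-1 fit; at 250 the default scheme puts
    {250, 400, 600, 800, 1000} above and {0, 30, 60, 90, 120} below.
    """

    b_threshold: float = 250.0
    constrained: bool = False
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    max_evals: int = 2000

    def validate(self, scheme: AcquisitionScheme) -> None:
        b = scheme.b_array
        n_hi = int(np.sum(b >= self.b_threshold))
        n_lo = int(np.sum(b < self.b_threshold))
        if n_hi < 3 or n_lo < 3:
            raise ValueError(
                f"b_threshold={self.b_threshold} leaves {n_hi} b-values above and "
                f"{n_lo} below; need at least 3 on each side"
            )


def _model(b: np.ndarray, s0: float, f: float, d: float, ds: float) -> np.ndarray:
    return s0 * (f * np.exp(-b * ds) + (1.0 - f) * np.exp(-b * d))


def _post_flags(p: IVIMParams, bounds: Dict[str, Tuple[float, float]]) -> IVIMParams:
    flags = []
    for name, val in (("s0", p.s0), ("f", p.f), ("d", p.d), ("d_star", p.d_star)):
        lo, hi = bounds[name]
        span = hi - lo
        if span > 0 and (abs(val - hi) < 1e-9 * span or (lo > 0 and abs(val - lo) < 1e-9 * span)):
            flags.append(AT_BOUND)
    if p.f <= _F_TINY or p.d_star <= p.d * (1.0 + 1e-3):
        flags.append(F_UNIDENTIFIABLE)
    if p.f <= _F_TINY and p.d < 1e-7:
        flags.append(DEGENERATE)  # flat signal: neither compartment decays
    return p.with_flags(*flags) if flags else p


def fit_voxel_free(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> IVIMParams:
    """Full 4-parameter nonlinear least-squares fit of one voxel.

    Minimises the sum of squared residuals over (S0, f, D, D*) inside box
    constraints, with D* >= D imposed through the parametrisation
    D* = D + delta, delta >= 0.  Three starts (the segmented estimate, a
    perturbed copy, and a generic mid-range point) guard against local
    minima; the lowest-residual solution wins, ties broken by lowest D*.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError("signal length must match the number of b-values")
    if len(scheme) < 5:
        raise ValueError("need at least 5 b-values for a 4-parameter fit")
    if not np.all(np.isfinite(signal)) or signal[0] <= 0:
        return IVIMParams(1.0, 0.0, 0.0, 0.0, valid=False, flags=frozenset({NO_CONVERGENCE}))
    b = scheme.b_array
    bnd = bounds or default_bounds(signal)

    def residual(x):
        s0, f, d, delta = x
        return _model(b, s0, f, d, d + delta) - signal

    lo = np.array([bnd["s0"][0], bnd["f"][0], bnd["d"][0], 0.0])
    hi = np.array([bnd["s0"][1], bnd["f"][1], bnd["d"][1], bnd["d_star"][1]])

    starts = _free_fit_starts(signal, scheme, bnd)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(
                residual, x0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        cost = float(sol.cost)
        ds = sol.x[2] + sol.x[3]
        if best is None or cost < best[0] - 1e-15 * (1 + abs(best[0])) or (
            abs(cost - best[0]) <= 1e-12 * (1 + abs(best[0])) and ds < best[2]
        ):
            best = (cost, sol, ds)
    if best is None:
        return IVIMParams(1.0, 0.0, 0.0, 0.0, valid=False, flags=frozenset({NO_CONVERGENCE}))
    _, sol, ds = best
    s0, f, d, _ = sol.x
    # when d* collapses onto d the two compartments are one exponential and f
    # is arbitrary along a flat cost valley: report the canonical
    # monoexponential form (f = 0) so downstream statistics see a stable value
    if ds <= d * (1.0 + 1e-3):
        f, ds = 0.0, float(d)
    p = IVIMParams(float(s0), float(f), float(d), float(ds), valid=bool(sol.success))
    if not sol.success:
        p = p.with_flags(NO_CONVERGENCE, valid=False)
    return _post_flags(p, bnd)


def _free_fit_starts(signal, scheme, bnd):
    seg = fit_voxel_segmented(signal, scheme, SegmentedConfig(bounds=bnd))
    starts = []
    if seg.valid:
        starts.append([seg.s0, seg.f, seg.d, max(seg.d_star - seg.d, 1e-6)])
        starts.append([seg.s0, min(seg.f * 1.3 + 0.01, 0.95), seg.d * 0.8,
                       max(3.0 * seg.d_star - seg.d, 1e-4)])
    starts.append([signal[0], 0.1, 1e-3, 10e-3])
    return starts


def fit_voxel_segmented(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    config: Optional[SegmentedConfig] = None,
) -> IVIMParams:
    """Two-stage segmented fit (unconstrained or constrained variant).

    Stage 1 fits ``ln m(b) = ln A - b D`` by weighted least squares on
    b >= b_threshold with weights m(b)^2 (the Gauss-Markov weighting for
    log-transformed noise), giving the tissue diffusion estimate and the
    high-b intercept A.  Stage 2 then either re-fits (S0, f, D*) with D
    fixed (unconstrained), or pins S0 = m(0) and f = 1 - A/m(0) and fits
    D* alone (constrained).  The stage-1 D estimate is always retained.
    """
    config = config or SegmentedConfig()
    config.validate(scheme)
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError("signal length must match the number of b-values")
    b = scheme.b_array
    m0 = signal[0]
    if not np.isfinite(m0) or m0 <= 0:
        return IVIMParams(1.0, 0.0, 0.0, 0.0, valid=False, flags=frozenset({STAGE1_FAILURE}))
    bnd = config.bounds or default_bounds(signal)

    hi_mask = b >= config.b_threshold
    m_hi, b_hi = signal[hi_mask], b[hi_mask]
    if np.any(m_hi <= 0) or not np.all(np.isfinite(m_hi)):
        return IVIMParams(m0, 0.0, 0.0, 0.0, valid=False, flags=frozenset({STAGE1_FAILURE}))

    # Weighted linear regression of log-signal on b (weights m^2).
    w = m_hi**2
    y = np.log(m_hi)
    W = np.sum(w)
    bw = np.sum(w * b_hi) / W
    yw = np.sum(w * y) / W
    denom = np.sum(w * (b_hi - bw) ** 2)
    if denom <= 0:
        return IVIMParams(m0, 0.0, 0.0, 0.0, valid=False, flags=frozenset({STAGE1_FAILURE}))
    slope = np.sum(w * (b_hi - bw) * (y - yw)) / denom
    d_hat = float(np.clip(-slope, bnd["d"][0], bnd["d"][1]))
    a_hat = float(np.exp(yw + slope * (-bw)))  # intercept at b=0

    flags = []
    f_from_intercept = 1.0 - a_hat / m0
    if f_from_intercept < 0.0:
        flags.append(AT_BOUND)
    f_hat = float(np.clip(f_from_intercept, 0.0, 1.0))

    ds_lo = max(d_hat, bnd["d_star"][0])
    ds_hi = bnd["d_star"][1]

    if config.constrained:
        s0_hat = float(m0)

        def resid_ds(x):
            return _model(b, s0_hat, f_hat, d_hat, x[0]) - signal

        if f_hat <= _F_TINY:
            # No perfusion signal: D* carries no information.
            p = IVIMParams(s0_hat, f_hat, d_hat, ds_lo, valid=True)
            return _post_flags(p.with_flags(*flags), bnd)
        sol = least_squares(resid_ds, [min(max(10e-3, ds_lo * 1.01), ds_hi)],
                            bounds=([ds_lo], [ds_hi]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=config.max_evals)
        p = IVIMParams(s0_hat, f_hat, d_hat, float(sol.x[0]), valid=bool(sol.success))
    else:
        def resid_su(x):
            s0, f, delta = x
            return _model(b, s0, f, d_hat, d_hat + delta) - signal

        lo = np.array([bnd["s0"][0], bnd["f"][0], 0.0])
        hi = np.array([bnd["s0"][1], bnd["f"][1], ds_hi])
        x0 = np.clip([m0, max(f_hat, 1e-3), 10e-3], lo + 1e-12, hi - 1e-12)
        sol = least_squares(resid_su, x0, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=config.max_evals)
        s0, f, delta = sol.x
        p = IVIMParams(float(s0), float(f), d_hat, float(d_hat + delta), valid=bool(sol.success))
    if not p.valid:
        flags.append(NO_CONVERGENCE)
    return _post_flags(p.with_flags(*flags) if flags else p, bnd)
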