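"""Synthetic DWI phantoms and two-timepoint patient cohorts.

No patient data accompany the study design this package implements, so every
pipeline input is simulated:

* **Phantoms** — an ellipsoidal "tumour" inside a 3D grid, with biexponential
  IVIM signals at the default 10-b acquisition and Rician magnitude noise at
  a stated SNR (= S0/sigma).  Ground-truth maps are returned alongside.

* **Cohorts** — per-patient ROI medians at baseline and after the first
  therapy cycle.  Baselines are log-normal around the published cohort
  medians; percentage changes are normal with group-specific medians and
  spreads calibrated so generated IQRs match the published interquartile
  ranges to first order.  The percentage change in Ki-67 is tied to the
  percentage change in perfusion fraction through a Gaussian copula whose
  rank correlation is the ``ki67_coupling`` parameter, so the cohort-level
  Spearman's rho is centred on the requested value (0.59 by default).

Defaults encode the study conditions: 8 good / 9 poor responders at
baseline, one good responder missing the Cycle-1 scan (7/9 at follow-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .model import AcquisitionScheme, IVIMParams, RicianNoiseModel, ivim_signal, rician_corrupt
from .roi import DwiSeries, ParametricMaps, RoiMask, RoiSummary
from .stats import CohortTable, PatientRecord

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]

# --------------------------------------------------------------------------
# Cohort distributional defaults (reporting units).
# Log-normal sigmas for baselines and normal sigmas for %changes are derived
# once from the published median (IQR) pairs via sigma = ln(q3/q1) / (2*z_.75)
# for log-normal and sigma = (q3 - q1) / (2*z_.75) for normal marginals.
_2Z75 = 2.0 * norm.ppf(0.75)  # 1.34898

BASELINE_MEDIANS = {"f": 10.81, "d": 0.95, "dstar": 6.20}
BASELINE_LOG_SIGMA = {
    "f": math.log(11.71 / 8.89) / _2Z75,
    "d": math.log(1.27 / 0.88) / _2Z75,
    "dstar": math.log(9.04 / 4.38) / _2Z75,
}
PCT_CHANGE_MEDIANS = {
    "good": {"f": -7.98, "d": 28.87, "dstar": -16.12},
    "poor": {"f": 10.04, "d": 15.54, "dstar": -14.89},
}
PCT_CHANGE_SIGMA = {
    "good": {"f": (1.73 + 19.47) / _2Z75, "d": (33.77 - 6.98) / _2Z75,
             "dstar": (17.05 - 3.50) / _2Z75},
    "poor": {"f": (28.93 - 5.09) / _2Z75, "d": (25.42 - 0.79) / _2Z75,
             "dstar": (24.98 - 4.12) / _2Z75},
}

# Ki-67: biopsy values bracket the published exemplars (17.5 and 23.7); the
# "survival ratio" w = 100 + %change(Ki-67) = 100 * excision / biopsy has a
# log-normal cohort marginal (so excision stays positive).
KI67_BIOPSY_RANGE = (10.0, 40.0)
KI67_W_MEDIAN = 35.0      # cohort median %change(Ki-67) of -65
KI67_W_LOG_SIGMA = 0.9


def _expected_sample_spearman(r: float, n: int) -> float:
    """E[sample Spearman rho] for n bivariate-normal pairs with correlation r.

    The exact finite-sample moment 6/(pi (n+1)) * ((n-2) asin(r/2) + asin r);
    the sample coefficient is attenuated relative to the population value
    (6/pi) asin(r/2), noticeably so at cohort-sized n.
    """
    return 6.0 / (math.pi * (n + 1)) * ((n - 2) * math.asin(r / 2.0) + math.asin(r))


def _latent_copula_r(spearman_rho: float, n: int) -> float:
    """Latent Gaussian-copula correlation whose *sample* Spearman's rho at
    size n has expectation ``spearman_rho`` (exact inversion of the
    bivariate-normal moment formula)."""
    if not -1.0 <= spearman_rho <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    if spearman_rho == 0.0:
        return 0.0
    from scipy.optimize import brentq
    lo, hi = (0.0, 1.0) if spearman_rho > 0 else (-1.0, 0.0)
    return float(brentq(lambda r: _expected_sample_spearman(r, n) - spearman_rho,
                        lo, hi, xtol=1e-12))


@dataclass
class PhantomSpec:
    """An ellipsoidal lesion with homogeneous (or field-valued) IVIM truth."""

    grid_shape: Tuple[int, int, int] = (16, 16, 4)
    lesion_center: Tuple[float, float, float] = (7.5, 7.5, 1.5)
    lesion_radii: Tuple[float, float, float] = (5.0, 5.0, 1.4)
    truth: Dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"s0": 1.0, "f": 0.1081, "d": 0.95e-3, "d_star": 6.20e-3}
    )
    snr: float = 50.0
    scheme: AcquisitionScheme = field(default_factory=AcquisitionScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.lesion_center = tuple(float(c) for c in self.lesion_center)
        self.lesion_radii = tuple(float(r) for r in self.lesion_radii)

    def validate(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        for c, r, n in zip(self.lesion_center, self.lesion_radii, self.grid_shape):
            if r <= 0 or c - r < -0.5 or c + r > n - 0.5:
                raise ValueError("lesion must lie within the grid")


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    grids = np.indices(spec.grid_shape).astype(float)
    q = sum(((g - c) / r) ** 2 for g, c, r in
            zip(grids, spec.lesion_center, spec.lesion_radii))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[DwiSeries, RoiMask, ParametricMaps]:
    """Simulate one DWI series: noise-free biexponential lesion + Rician noise.

    Returns the noisy series, the lesion mask, and ground-truth parametric
    maps in reporting units.  Background voxels have zero true signal, so
    their magnitudes are pure Rayleigh noise.  Deterministic given the seed.
    """
    spec.validate()
    mask = _ellipsoid_mask(spec)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    shape = spec.grid_shape
    nb = len(spec.scheme)

    def _field(name) -> np.ndarray:
        v = spec.truth[name]
        arr = np.asarray(v, dtype=float)
        return np.broadcast_to(arr, shape).copy()

    s0_f, f_f, d_f, ds_f = (_field(n) for n in ("s0", "f", "d", "d_star"))
    b = spec.scheme.b_array
    clean = np.zeros(shape + (nb,))
    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        clean[i, j, k] = s0_f[i, j, k] * (
            f_f[i, j, k] * np.exp(-b * ds_f[i, j, k])
            + (1.0 - f_f[i, j, k]) * np.exp(-b * d_f[i, j, k])
        )
    sigma = float(np.median(s0_f[mask])) / spec.snr
    rng = np.random.default_rng(spec.seed)
    noisy = rician_corrupt(clean, RicianNoiseModel(sigma), rng)

    dwi = DwiSeries(volumes=noisy, scheme=spec.scheme)
    sent = np.full(shape, np.nan)
    truth = ParametricMaps(
        f_map=np.where(mask, f_f * 100.0, sent),
        d_map=np.where(mask, d_f * 1e3, sent),
        dstar_map=np.where(mask, ds_f * 1e3, sent),
        valid_map=mask,
        method="truth",
    )
    return dwi, RoiMask(mask), truth


@dataclass
class CohortSpec:
    """Distributional recipe for a synthetic two-timepoint cohort."""

    n_good: int = 8
    n_poor: int = 9
    baseline_medians: Dict[str, float] = field(default_factory=lambda: dict(BASELINE_MEDIANS))
    baseline_log_sigma: Dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_LOG_SIGMA))
    pct_change_medians: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in PCT_CHANGE_MEDIANS.items()})
    pct_change_sigma: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in PCT_CHANGE_SIGMA.items()})
    ki67_coupling: float = 0.59
    drop_one_good_cycle1: bool = True   # one patient missed the Cycle-1 scan
    fidelity: str = "summary"           # "summary" or "voxel"
    phantom_snr: float = 50.0
    phantom_grid: Tuple[int, int, int] = (12, 12, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        self.phantom_grid = tuple(int(n) for n in self.phantom_grid)

    def validate(self) -> None:
        if self.n_good < 1 or self.n_poor < 1:
            raise ValueError("group sizes must be >= 1")
        if not -1.0 <= self.ki67_coupling <= 1.0:
            raise ValueError("ki67_coupling must lie in [-1, 1]")
        for g in ("good", "poor"):
            if any(s <= 0 for s in self.pct_change_sigma[g].values()):
                raise ValueError("dispersion must be positive")
        if any(s <= 0 for s in self.baseline_log_sigma.values()):
            raise ValueError("dispersion must be positive")
        if abs(self.ki67_coupling) == 1.0:
            raise ValueError("|coupling| = 1 is infeasible with positive noise")
        if self.fidelity not in ("summary", "voxel"):
            raise ValueError("fidelity must be 'summary' or 'voxel'")


def _mixture_cdf(x: np.ndarray, groups, spec: CohortSpec) -> np.ndarray:
    """Pooled CDF of %change(f) across the two responder groups."""
    w_good = np.mean(np.asarray(groups) == "good")
    mg, sg = spec.pct_change_medians["good"]["f"], spec.pct_change_sigma["good"]["f"]
    mp, sp = spec.pct_change_medians["poor"]["f"], spec.pct_change_sigma["poor"]["f"]
    return w_good * norm.cdf(x, mg, sg) + (1 - w_good) * norm.cdf(x, mp, sp)


def generate_cohort(spec: Optional[CohortSpec] = None):
    """Draw one synthetic cohort.

    Returns a :class:`~ivimtools.stats.CohortTable`; with
    ``fidelity="voxel"`` returns ``(table, phantoms)`` where ``phantoms``
    maps ``(patient_id, timepoint)`` to ``(DwiSeries, RoiMask, truth maps)``
    whose homogeneous lesion truth equals that visit's generated medians.

    The Ki-67 coupling uses a Gaussian copula at cohort level: each
    patient's %change(f) is mapped through the pooled mixture CDF to a
    normal score, a second score is drawn with latent correlation
    ``2 sin(pi * rho / 6)`` (the inverse of the normal-copula Spearman
    formula), and mapped through the log-normal marginal of the Ki-67
    survival ratio.  Setting the coupling to 0 makes the two markers
    independent.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_good + spec.n_poor
    groups = ["good"] * spec.n_good + ["poor"] * spec.n_poor

    grades = np.where(
        np.array(groups) == "good",
        rng.integers(4, 6, size=n),
        rng.integers(1, 4, size=n),
    )

    base = {m: spec.baseline_medians[m]
            * np.exp(spec.baseline_log_sigma[m] * rng.standard_normal(n))
            for m in ("f", "d", "dstar")}

    z1 = rng.standard_normal(n)
    pct = {}
    for m in ("f", "d", "dstar"):
        z = z1 if m == "f" else rng.standard_normal(n)
        mu = np.array([spec.pct_change_medians[g][m] for g in groups])
        sd = np.array([spec.pct_change_sigma[g][m] for g in groups])
        pct[m] = np.clip(mu + sd * z, -95.0, None)

    # Gaussian copula between %change(f) and the Ki-67 survival ratio;
    # the latent correlation is calibrated so the *sample* Spearman's rho
    # at the realised follow-up size is centred on the requested coupling.
    n_cycle1 = n - (1 if (spec.drop_one_good_cycle1 and spec.n_good > 0) else 0)
    r = _latent_copula_r(spec.ki67_coupling, max(n_cycle1, 4))
    q = norm.ppf(np.clip(_mixture_cdf(pct["f"], groups, spec), 1e-12, 1 - 1e-12))
    z2 = r * q + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    w = KI67_W_MEDIAN * np.exp(KI67_W_LOG_SIGMA * z2)  # 100 * excision/biopsy
    biopsy = rng.uniform(*KI67_BIOPSY_RANGE, size=n)
    excision = np.clip(biopsy * w / 100.0, 0.0, 100.0)

    drop_idx = 0 if (spec.drop_one_good_cycle1 and spec.n_good > 0) else -1

    records = []
    for i in range(n):
        baseline = RoiSummary(
            f_median=float(base["f"][i]), d_median=float(base["d"][i]),
            dstar_median=float(base["dstar"][i]),
            n_voxels_total=100, n_voxels_valid=100,
        )
        cycle1 = None
        if i != drop_idx:
            cycle1 = RoiSummary(
                f_median=float(base["f"][i] * (1 + pct["f"][i] / 100.0)),
                d_median=float(base["d"][i] * (1 + pct["d"][i] / 100.0)),
                dstar_median=float(base["dstar"][i] * (1 + pct["dstar"][i] / 100.0)),
                n_voxels_total=100, n_voxels_valid=100,
            )
        records.append(PatientRecord(
            patient_id=f"P{i + 1:02d}",
            miller_payne_grade=int(grades[i]),
            ki67_biopsy=float(biopsy[i]),
            ki67_excision=float(excision[i]),
            baseline=baseline,
            cycle1=cycle1,
        ))
    table = CohortTable(records)
    if spec.fidelity == "summary":
        return table

    phantoms = {}
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * n)
    for i, rec in enumerate(records):
        for t, summ in (("baseline", rec.baseline), ("cycle1", rec.cycle1)):
            if summ is None:
                continue
            pspec = PhantomSpec(
                grid_shape=spec.phantom_grid,
                lesion_center=tuple((s - 1) / 2.0 for s in spec.phantom_grid),
                lesion_radii=(spec.phantom_grid[0] * 0.32,
                              spec.phantom_grid[1] * 0.32,
                              max(spec.phantom_grid[2] * 0.4, 0.6)),
                truth={"s0": 1.0, "f": summ.f_median / 100.0,
                       "d": summ.d_median * 1e-3, "d_star": summ.dstar_median * 1e-3},
                snr=spec.phantom_snr,
                seed=int(child_seeds[2 * i + (t == "cycle1")]),
            )
            dwi, mask, truth = generate_phantom(pspec)
            dwi.patient_id = rec.patient_id
            dwi.timepoint = t
            phantoms[(rec.patient_id, t)] = (dwi, mask, truth)
    return table, phantoms
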