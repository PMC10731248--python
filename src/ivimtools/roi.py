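"""From 4D DWI series and tumour masks to parametric maps and ROI markers.

The within-tumour workflow: average the per-direction acquisitions, fit the
selected estimator voxel-by-voxel inside the mask, convert to reporting units
(f in %, D and D* in 1e-3 mm^2/s), take ROI medians over valid voxels, and
form the longitudinal percentage-change markers

    %change = [Cycle1 - Baseline] / Baseline * 100

per parameter.  Voxels the estimator cannot fit are excluded from medians and
counted; voxels outside the mask carry NaN sentinels, never silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .model import AcquisitionScheme, IVIMParams
from .bayes import McmcConfig, UnfittableVoxelError, fit_voxel_bayesian
from .conventional import SegmentedConfig, fit_voxel_free, fit_voxel_segmented

__all__ = [
    "METHODS",
    "DwiSeries",
    "RoiMask",
    "ParametricMaps",
    "RoiSummary",
    "average_directions",
    "fit_map",
    "roi_median",
    "percent_change",
    "resample_mask_nearest",
]

logger = logging.getLogger(__name__)

#: The four analysis arms.
METHODS = ("bayesian", "free", "segmented_unconstrained", "segmented_constrained")

SENTINEL = np.nan


@dataclass
class DwiSeries:
    """A 4D diffusion-weighted series (x, y, z, b) with its scheme."""

    volumes: np.ndarray
    scheme: AcquisitionScheme
    voxel_size_mm: Tuple[float, float, float] = (2.5, 2.5, 5.0)
    patient_id: str = ""
    timepoint: str = "baseline"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        if v.ndim != 4:
            raise ValueError(f"volumes must be 4D (x, y, z, b), got {v.ndim}D")
        if v.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension has {v.shape[3]} volumes but the scheme has "
                f"{len(self.scheme)} b-values"
            )
        if np.any(v < 0):
            raise ValueError("magnitude volumes must be non-negative")
        self.volumes = v
        if self.timepoint not in ("baseline", "cycle1"):
            raise ValueError("timepoint must be 'baseline' or 'cycle1'")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.volumes.shape[:3]


@dataclass
class RoiMask:
    """Binary tumour mask on the DWI voxel grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if not m.any():
            raise ValueError("mask is empty")
        self.mask = m

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ParametricMaps:
    """Voxel maps of f/D/D* in reporting units plus a validity map.

    f_map is in %, d_map and dstar_map in 1e-3 mm^2/s; voxels that were not
    fit (outside the mask) or failed to fit carry NaN, with valid_map False.
    """

    f_map: np.ndarray
    d_map: np.ndarray
    dstar_map: np.ndarray
    valid_map: np.ndarray
    method: str
    timepoint: str = "baseline"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.f_map, self.d_map, self.dstar_map, self.valid_map)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one spatial shape")
        self.valid_map = np.asarray(self.valid_map).astype(bool)


@dataclass
class RoiSummary:
    """Within-ROI medians in reporting units with voxel accounting."""

    f_median: float
    d_median: float
    dstar_median: float
    n_voxels_total: int
    n_voxels_valid: int

    def __post_init__(self) -> None:
        if self.n_voxels_valid < 1:
            raise ValueError("a reportable summary needs at least one valid voxel")


def average_directions(per_direction: np.ndarray, scheme: AcquisitionScheme,
                       **series_kwargs) -> DwiSeries:
    """Average a 5D (x, y, z, b, direction) acquisition over directions."""
    v = np.asarray(per_direction, dtype=float)
    if v.ndim != 5:
        raise ValueError(f"expected 5D (x, y, z, b, direction), got {v.ndim}D")
    if v.shape[4] < 1:
        raise ValueError("direction axis must have length >= 1")
    return DwiSeries(volumes=v.mean(axis=4), scheme=scheme, **series_kwargs)


def _fit_one(signal: np.ndarray, scheme: AcquisitionScheme, method: str,
             mcmc_config: Optional[McmcConfig], seg_config: Optional[SegmentedConfig],
             seed: Optional[int]) -> IVIMParams:
    if method == "bayesian":
        cfg = mcmc_config or McmcConfig()
        if seed is not None:
            from dataclasses import replace
            cfg = replace(cfg, seed=seed)
        return fit_voxel_bayesian(signal, scheme, cfg)
    if method == "free":
        return fit_voxel_free(signal, scheme)
    if method in ("segmented_unconstrained", "segmented_constrained"):
        base = seg_config or SegmentedConfig()
        from dataclasses import replace
        cfg = replace(base, constrained=(method == "segmented_constrained"))
        return fit_voxel_segmented(signal, scheme, cfg)
    raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")


def fit_map(
    dwi: DwiSeries,
    roi: RoiMask,
    method: str = "bayesian",
    mcmc_config: Optional[McmcConfig] = None,
    seg_config: Optional[SegmentedConfig] = None,
) -> ParametricMaps:
    """Fit the selected estimator at every masked voxel.

    Only masked voxels are fit (the cohort statistics are within-tumour
    medians, and MCMC over a whole volume would be wasteful); unmasked
    voxels keep the NaN sentinel.  For the Bayesian arm each voxel's chain
    seed is derived deterministically from the config seed and the voxel's
    flat index, so maps are reproducible and voxels independent.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    if roi.mask.shape != dwi.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match DWI grid {dwi.shape}"
        )
    shape = dwi.shape
    f_map = np.full(shape, SENTINEL)
    d_map = np.full(shape, SENTINEL)
    ds_map = np.full(shape, SENTINEL)
    valid = np.zeros(shape, dtype=bool)

    base_seed = (mcmc_config.seed if mcmc_config is not None else 0)
    idx = np.argwhere(roi.mask)
    n_failed = 0
    for (i, j, k) in idx:
        signal = dwi.volumes[i, j, k, :]
        flat = int(np.ravel_multi_index((i, j, k), shape))
        seed = (int(base_seed) * 1_000_003 + flat) % (2**31) if method == "bayesian" else None
        try:
            p = _fit_one(signal, dwi.scheme, method, mcmc_config, seg_config, seed)
        except UnfittableVoxelError:
            n_failed += 1
            continue
        if not p.valid:
            n_failed += 1
            continue
        f_pct, d_r, ds_r = p.to_reporting_units()
        f_map[i, j, k] = f_pct
        d_map[i, j, k] = d_r
        ds_map[i, j, k] = ds_r
        valid[i, j, k] = True
    if n_failed:
        logger.info("fit_map(%s): %d/%d masked voxels could not be fit",
                    method, n_failed, len(idx))
    return ParametricMaps(f_map, d_map, ds_map, valid, method=method,
                          timepoint=dwi.timepoint, affine=dwi.affine)


def roi_median(maps: ParametricMaps, roi: RoiMask) -> RoiSummary:
    """Median f/D/D* over valid masked voxels (midpoint convention for even n)."""
    if roi.mask.shape != maps.f_map.shape:
        raise ValueError("mask and maps are on different grids")
    sel = roi.mask & maps.valid_map
    n_valid = int(sel.sum())
    if n_valid == 0:
        raise ValueError(
            f"no valid voxels in ROI ({roi.n_voxels} masked, 0 fit successfully)"
        )
    return RoiSummary(
        f_median=float(np.median(maps.f_map[sel])),
        d_median=float(np.median(maps.d_map[sel])),
        dstar_median=float(np.median(maps.dstar_map[sel])),
        n_voxels_total=roi.n_voxels,
        n_voxels_valid=n_valid,
    )


def percent_change(baseline: RoiSummary, cycle1: RoiSummary) -> Dict[str, float]:
    """Signed percentage change of each ROI median from baseline to Cycle 1."""
    out = {}
    for name, b, c in (
        ("f", baseline.f_median, cycle1.f_median),
        ("d", baseline.d_median, cycle1.d_median),
        ("d_star", baseline.dstar_median, cycle1.dstar_median),
    ):
        if b == 0:
            raise ZeroDivisionError(f"baseline {name} median is zero; %change undefined")
        out[name] = (c - b) / b * 100.0
    return out


def resample_mask_nearest(mask: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask to another grid.

    Convenience utility only: masks are expected to arrive already on the
    DWI grid (the resolution-matching step is upstream of this package).
    """
    mask = np.asarray(mask).astype(bool)
    idx = [np.minimum((np.arange(t) + 0.5) * s / t, s - 1).astype(int)
           for s, t in zip(mask.shape, target_shape)]
    return mask[np.ix_(*idx)]
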