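"""File formats: NIfTI-1 volumes, FSL-dialect bval text, cohort CSV, YAML config.

DWI series and masks are exchanged as NIfTI-1 with the b-value table in a
whitespace-separated text file (FSL bval dialect).  Parametric maps are
written one NIfTI per parameter (reporting units) plus a validity volume,
with the method and timepoint embedded in the filename.  Affines are assumed
RAS-positive and are never reoriented: a mismatch between DWI and mask
affines is a hard error, because silent resampling would corrupt the ROI
statistics.  Cohort tables travel as comma-separated UTF-8 CSV with a
mandatory header and empty fields for missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bayes import McmcConfig
from .conventional import SegmentedConfig
from .model import AcquisitionScheme
from .roi import DwiSeries, ParametricMaps, RoiMask

__all__ = [
    "read_bvals", "write_bvals", "read_dwi", "write_dwi",
    "read_mask", "write_mask", "write_maps", "read_maps",
    "cohort_to_csv", "cohort_from_csv", "PipelineConfig", "FormatError",
]

#: Mandatory columns of the clinical/cohort CSV.
COHORT_REQUIRED = (
    "patient_id", "mp_grade", "ki67_biopsy", "ki67_excision",
    "f_baseline", "d_baseline", "dstar_baseline",
)


class FormatError(ValueError):
    """A file did not match the expected on-disk format."""


def read_bvals(path) -> Tuple[float, ...]:
    text = Path(path).read_text()
    try:
        return tuple(float(tok) for tok in text.split())
    except ValueError as e:
        raise FormatError(f"bval file {path} is not whitespace-separated numbers: {e}")


def write_bvals(path, scheme: AcquisitionScheme) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")


def read_dwi(nifti_path, bval_path, **series_kwargs) -> DwiSeries:
    """Load a 4D NIfTI plus its bval table into a DwiSeries."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4D series, got {data.ndim}D")
    bvals = read_bvals(bval_path)
    if len(bvals) != data.shape[3]:
        raise FormatError(
            f"bval file lists {len(bvals)} values but {nifti_path} holds "
            f"{data.shape[3]} volumes"
        )
    zooms = img.header.get_zooms()[:3]
    return DwiSeries(
        volumes=data, scheme=AcquisitionScheme(b_values=bvals),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine), **series_kwargs,
    )


def write_dwi(dwi: DwiSeries, nifti_path, bval_path) -> None:
    nib.save(nib.Nifti1Image(dwi.volumes, dwi.affine), str(nifti_path))
    write_bvals(bval_path, dwi.scheme)


def read_mask(path, expect_affine: Optional[np.ndarray] = None) -> RoiMask:
    img = nib.load(str(path))
    if expect_affine is not None and not np.allclose(img.affine, expect_affine, atol=1e-4):
        raise FormatError(
            f"mask affine of {path} differs from the DWI affine; "
            "resample upstream, no silent reorientation is performed"
        )
    return RoiMask(np.asarray(img.get_fdata()) > 0.5)


def write_mask(mask: RoiMask, path, affine: Optional[np.ndarray] = None) -> None:
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), aff), str(path))


def _map_path(out_dir: Path, method: str, timepoint: str, name: str) -> Path:
    return out_dir / f"{method}_{timepoint}_{name}.nii"


def write_maps(maps: ParametricMaps, out_dir) -> Dict[str, Path]:
    """One NIfTI per parameter (f %, D and D* 1e-3 mm^2/s) plus validity."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = maps.affine if maps.affine is not None else np.eye(4)
    paths = {}
    for name, arr in (("f", maps.f_map), ("d", maps.d_map),
                      ("dstar", maps.dstar_map)):
        p = _map_path(out_dir, maps.method, maps.timepoint, name)
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), str(p))
        paths[name] = p
    p = _map_path(out_dir, maps.method, maps.timepoint, "valid")
    nib.save(nib.Nifti1Image(maps.valid_map.astype(np.uint8), aff), str(p))
    paths["valid"] = p
    return paths


def read_maps(out_dir, method: str, timepoint: str = "baseline") -> ParametricMaps:
    out_dir = Path(out_dir)
    arrays = {}
    for name in ("f", "d", "dstar", "valid"):
        p = _map_path(out_dir, method, timepoint, name)
        if not p.exists():
            raise FormatError(f"missing map file {p}")
        arrays[name] = np.asarray(nib.load(str(p)).get_fdata())
    aff = np.asarray(nib.load(str(_map_path(out_dir, method, timepoint, "f"))).affine)
    return ParametricMaps(arrays["f"], arrays["d"], arrays["dstar"],
                          arrays["valid"] > 0.5, method=method,
                          timepoint=timepoint, affine=aff)


def cohort_to_csv(cohort, path) -> None:
    from .stats import CohortTable
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    df.to_csv(path, index=False, encoding="utf-8")


def cohort_from_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV, deriving %change columns when absent."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"cohort CSV {path} is missing required column(s): {', '.join(missing)}"
        )
    from .stats import assign_response_group, ki67_percent_change
    if "group" not in df.columns:
        df["group"] = df["mp_grade"].map(assign_response_group)
    for m in ("f", "d", "dstar"):
        base, c1, pc = f"{m}_baseline", f"{m}_cycle1", f"pct_change_{m}"
        if pc not in df.columns and c1 in df.columns:
            df[pc] = (df[c1] - df[base]) / df[base] * 100.0
    if "pct_change_ki67" not in df.columns:
        df["pct_change_ki67"] = [
            ki67_percent_change(b, e)
            for b, e in zip(df["ki67_biopsy"], df["ki67_excision"])
        ]
    return df


# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Bundled settings for a pipeline run; serialises to/from YAML."""

    method: str = "bayesian"
    seed: int = 0
    b_values: Tuple[float, ...] = AcquisitionScheme().b_values
    mcmc: Dict = field(default_factory=dict)
    segmented: Dict = field(default_factory=dict)
    phantom: Dict = field(default_factory=dict)
    cohort: Dict = field(default_factory=dict)
    log_level: str = "INFO"

    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(b_values=self.b_values)

    def mcmc_config(self) -> McmcConfig:
        cfg = McmcConfig(**self.mcmc)
        cfg.seed = self.seed
        cfg.validate()
        return cfg

    def segmented_config(self) -> SegmentedConfig:
        return SegmentedConfig(**self.segmented)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["b_values"] = list(d["b_values"])
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        if "b_values" in d:
            d["b_values"] = tuple(d["b_values"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
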