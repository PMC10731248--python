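"""Biexponential IVIM signal model and Rician magnitude-noise model.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MR signal of a voxel as the sum of two independently attenuating compartments:
capillary blood whose pseudo-random flow appears as a fast pseudodiffusion
``D*``, and extravascular tissue water with a slow diffusion coefficient ``D``.
The perfusion fraction ``f`` is the signal-volume fraction of the blood pool:

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

Magnitude MR images carry Rician noise (the modulus of a complex Gaussian),
which is the likelihood every estimator in this package uses.  No noise-floor
bias correction is applied anywhere: magnitudes are modelled as Rician exactly,
never "corrected" before fitting.

Unit convention: ``d`` and ``d_star`` are held in mm^2/s internally and ``f``
as a fraction in [0, 1].  The conventional reporting units (f in %, D and D*
in 1e-3 mm^2/s) are applied only at the reporting boundary (see
:func:`IVIMParams.to_reporting_units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Sequence, Tuple

import numpy as np
from scipy import special

__all__ = [
    "DEFAULT_B_VALUES",
    "AcquisitionScheme",
    "IVIMParams",
    "RicianNoiseModel",
    "ivim_signal",
    "rician_logpdf",
    "rician_corrupt",
]

#: The 10-b-value breast protocol used as the default scheme, in s/mm^2.
DEFAULT_B_VALUES: Tuple[float, ...] = (
    0.0, 30.0, 60.0, 90.0, 120.0, 250.0, 400.0, 600.0, 800.0, 1000.0,
)

# Degeneracy / validity flags attached to fit results.
F_UNIDENTIFIABLE = "F_UNIDENTIFIABLE"  # f ~ 0, so d_star carries no information
AT_BOUND = "AT_BOUND"                  # estimate landed on a box constraint
DEGENERATE = "DEGENERATE"              # flat/constant signal, d ~ d* ~ 0
STAGE1_FAILURE = "STAGE1_FAILURE"      # segmented high-b stage failed
NO_CONVERGENCE = "NO_CONVERGENCE"


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion weightings and sequence metadata shared by all estimators.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm^2; must be non-negative, strictly
        increasing and start at 0.
    n_directions
        Number of orthogonal gradient directions averaged per b-value
        (metadata only).
    delta_small_ms, delta_big_ms
        Gradient duration / separation in ms (metadata only).
    te_ms, tr_ms
        Echo / repetition time in ms (metadata only).
    """

    b_values: Tuple[float, ...] = DEFAULT_B_VALUES
    n_directions: int = 3
    delta_small_ms: float = 13.1
    delta_big_ms: float = 25.4
    te_ms: float = 50.0
    tr_ms: float = 2400.0

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        object.__setattr__(self, "b_values", b)
        if len(b) == 0:
            raise ValueError("b_values must be non-empty")
        if b[0] != 0.0:
            raise ValueError(f"first b-value must be 0, got {b[0]}")
        arr = np.asarray(b)
        if np.any(arr < 0):
            raise ValueError("b_values must be non-negative")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("b_values must be strictly increasing")

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    def __len__(self) -> int:
        return len(self.b_values)


@dataclass
class IVIMParams:
    """One voxel's IVIM parameter set, in internal units.

    ``s0`` is the b=0 amplitude (arbitrary units), ``f`` the perfusion
    fraction in [0, 1], ``d`` and ``d_star`` the tissue diffusion and
    pseudodiffusion coefficients in mm^2/s.
    """

    s0: float
    f: float
    d: float
    d_star: float
    valid: bool = True
    flags: FrozenSet[str] = field(default_factory=frozenset)

    def validate(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.d < 0.0:
            raise ValueError(f"d must be non-negative, got {self.d}")
        if self.d_star < 0.0:
            raise ValueError(f"d_star must be non-negative, got {self.d_star}")
        if self.valid and not self.s0 > 0.0:
            raise ValueError(f"s0 must be positive for a valid fit, got {self.s0}")

    def with_flags(self, *flags: str, valid: bool | None = None) -> "IVIMParams":
        new_valid = self.valid if valid is None else valid
        return replace(self, flags=self.flags | frozenset(flags), valid=new_valid)

    def to_reporting_units(self) -> Tuple[float, float, float]:
        """Return (f in %, D in 1e-3 mm^2/s, D* in 1e-3 mm^2/s)."""
        return self.f * 100.0, self.d * 1e3, self.d_star * 1e3


@dataclass(frozen=True)
class RicianNoiseModel:
    """Rician magnitude noise with scale ``sigma`` (signal units)."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def ivim_signal(params: IVIMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Evaluate the biexponential IVIM signal at each b-value of ``scheme``.

    Returns an array of non-negative signal values, one per b-value; the value
    at b=0 equals ``params.s0`` exactly, and the curve is non-increasing in b
    for non-negative coefficients.
    """
    params.validate()
    b = scheme.b_array
    return params.s0 * (
        params.f * np.exp(-b * params.d_star)
        + (1.0 - params.f) * np.exp(-b * params.d)
    )


def rician_logpdf(
    measured: np.ndarray | float,
    predicted: np.ndarray | float,
    noise: RicianNoiseModel,
) -> np.ndarray | float:
    """Log-density of the Rice distribution, overflow-safe.

    ``p(m | nu, sigma) = m/sigma^2 * exp(-(m^2 + nu^2)/(2 sigma^2)) * I0(m nu / sigma^2)``

    evaluated with the exponentially scaled Bessel function ``i0e`` so that
    large SNR arguments do not overflow.  ``predicted`` (nu) is the noise-free
    signal; at nu=0 the density reduces to a Rayleigh distribution.
    """
    m = np.asarray(measured, dtype=float)
    nu = np.asarray(predicted, dtype=float)
    if np.any(m < 0):
        raise ValueError("measured magnitudes must be non-negative")
    if np.any(nu < 0):
        raise ValueError("predicted noise-free values must be non-negative")
    s2 = noise.sigma**2
    z = m * nu / s2
    # log I0(z) = z + log(i0e(z)); the explicit +z cancels the growth of I0.
    with np.errstate(divide="ignore"):
        out = (
            np.log(m) - np.log(s2) - (m**2 + nu**2) / (2.0 * s2)
            + z + np.log(special.i0e(z))
        )
    if out.ndim == 0:
        return float(out)
    return out


def rician_corrupt(
    signal: Sequence[float] | np.ndarray,
    noise: RicianNoiseModel,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Corrupt a noise-free signal with Rician noise.

    Each output magnitude is ``sqrt((s + g1*sigma)^2 + (g2*sigma)^2)`` with
    g1, g2 independent standard normal draws — the modulus of a complex
    Gaussian centred on the true signal.  Deterministic given an integer seed
    or a seeded Generator.
    """
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("signal values must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    g = rng.standard_normal(size=(2,) + s.shape)
    return np.hypot(s + noise.sigma * g[0], noise.sigma * g[1])
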