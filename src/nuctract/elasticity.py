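"""Shared continuum-elasticity types and constitutive relations.

Stress follows the linear Hooke law
``σ_ij = E/(1+ν) (ε_ij + ν/(1−2ν) ε_kk δ_ij)``.  The incompressible case
ν = 0.5 is handled exactly: the trace term is dropped because the strain is
trace-free by construction (z-closure), giving ``σ = (2E/3) ε``; a strain
with non-vanishing trace at ν = 0.5 is an error, never a ν→0.4999 hack.

Strain conventions: ``"as-printed"`` keeps an extra factor ½ on the
quadratic displacement-gradient term, ``"green-lagrange"`` is the standard
rotation-invariant finite-strain tensor.  Both are supported everywhere via
one flag; neither is silently preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour import Contour
from .errors import ContourError, IncompressibilityError, MeshError
from .geometry import FrameField

STRAIN_CONVENTIONS = ("as-printed", "green-lagrange")
_TRACE_TOL = 1e-9
_NORMAL_TOL = 1e-9

__all__ = [
    "ElasticParams",
    "PointMapping",
    "StrainField",
    "StressField",
    "TractionProfile",
    "stress_from_strain",
    "energy_density",
    "traction",
    "quadratic_factor",
]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic material parameters.

    E: Young's modulus (Pa); nu: Poisson ratio (0.5 = incompressible);
    h: shell thickness (μm, shell model only); strain_convention: see module
    docstring.
    """

    E: float = 5000.0
    nu: float = 0.5
    h: float = 0.1
    strain_convention: str = "as-printed"

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.nu <= 0.5:
            raise ValueError("Poisson ratio must be in (0, 0.5]")
        if self.h <= 0:
            raise ValueError("shell thickness must be positive")
        if self.strain_convention not in STRAIN_CONVENTIONS:
            raise ValueError(
                f"strain_convention must be one of {STRAIN_CONVENTIONS}"
            )


def quadratic_factor(convention: str) -> float:
    """Coefficient q in ε = ½(g + gᵀ + q gᵀg): ½ as printed, 1 for Green–Lagrange."""
    if convention not in STRAIN_CONVENTIONS:
        raise ValueError(f"unknown strain convention {convention!r}")
    return 0.5 if convention == "as-printed" else 1.0


@dataclass(frozen=True)
class PointMapping:
    """Per-point correspondence between an initial and a target contour.

    Both contours have the same point count and anticlockwise order;
    ``u = target - initial`` is the boundary deformation field (μm).
    """

    initial: Contour
    target: Contour

    def __post_init__(self) -> None:
        if len(self.initial) != len(self.target):
            raise ContourError(
                f"mapping point counts differ: {len(self.initial)} vs {len(self.target)}"
            )

    def __len__(self) -> int:
        return len(self.initial)

    @property
    def u(self) -> np.ndarray:
        return self.target.points - self.initial.points


@dataclass(frozen=True)
class StrainField:
    """Per-point symmetric 3×3 strain tensors.

    ``basis`` is ``"cartesian"`` (x, y, z) or ``"surface"`` (n, s1, s2).
    """

    tensors: np.ndarray = field(repr=False)
    basis: str = "cartesian"

    def __post_init__(self) -> None:
        t = np.asarray(self.tensors, dtype=float)
        if t.shape[-2:] != (3, 3):
            raise MeshError(f"expected (..., 3, 3) tensors, got {t.shape}")
        sym = 0.5 * (t + np.swapaxes(t, -1, -2))
        object.__setattr__(self, "tensors", sym)

    @property
    def trace(self) -> np.ndarray:
        return np.einsum("...ii->...", self.tensors)


@dataclass(frozen=True)
class StressField:
    """Per-point symmetric 3×3 stress tensors (Pa)."""

    tensors: np.ndarray = field(repr=False)
    basis: str = "cartesian"


def stress_from_strain(strain: StrainField, params: ElasticParams) -> StressField:
    """Hooke law; exact incompressible branch at ν = 0.5 (requires ε_kk ≈ 0)."""
    eps = strain.tensors
    if params.nu == 0.5:
        tr = np.einsum("...ii->...", eps)
        worst = float(np.max(np.abs(tr))) if tr.size else 0.0
        if worst >= _TRACE_TOL:
            raise IncompressibilityError(
                f"strain trace {worst:.3e} >= {_TRACE_TOL} at nu = 0.5"
            )
        sigma = (2.0 * params.E / 3.0) * eps
    else:
        tr = np.einsum("...ii->...", eps)
        eye = np.eye(3)
        sigma = (params.E / (1.0 + params.nu)) * (
            eps + (params.nu / (1.0 - 2.0 * params.nu)) * tr[..., None, None] * eye
        )
    return StressField(sigma, basis=strain.basis)


def energy_density(strain: StrainField, stress: StressField) -> np.ndarray:
    """Free-energy density f = ½ σ_ij ε_ij (J/m³ ≡ Pa), pointwise."""
    if strain.tensors.shape != stress.tensors.shape:
        raise MeshError(
            f"mismatched field shapes {strain.tensors.shape} vs {stress.tensors.shape}"
        )
    if strain.basis != stress.basis:
        raise MeshError("strain and stress are in different bases")
    return 0.5 * np.einsum("...ij,...ij->...", stress.tensors, strain.tensors)


@dataclass(frozen=True)
class TractionProfile:
    """Per-boundary-point traction (Pa) parametrized by arclength."""

    s1: np.ndarray = field(repr=False)
    points: np.ndarray = field(repr=False)
    traction_vec: np.ndarray = field(repr=False)
    energy: np.ndarray = field(repr=False)
    model: str = ""

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.traction_vec, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s1_um": self.s1,
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "tx_Pa": self.traction_vec[:, 0],
                "ty_Pa": self.traction_vec[:, 1],
                "tmag_Pa": self.magnitude,
                "f_J_per_m3": self.energy,
                "model": self.model,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def traction(stress: StressField, frames: FrameField) -> np.ndarray:
    """Surface traction t_i = σ_ij n_j from in-plane Cartesian stress.

    Only the in-plane stress block contributes: the outline normal is
    perpendicular to z, so σ_zz never enters.  Returns (N, 2) vectors (Pa).
    """
    sig = stress.tensors
    if stress.basis != "cartesian":
        raise MeshError("traction requires Cartesian stress")
    if sig.ndim != 3 or sig.shape[0] != len(frames):
        raise MeshError(
            f"stress must be per boundary point: {sig.shape} vs {len(frames)} points"
        )
    n = frames.normal
    norms = np.linalg.norm(n, axis=1)
    if np.any(np.abs(norms - 1.0) > _NORMAL_TOL):
        raise ContourError("normals must be unit length")
    return np.einsum("kij,kj->ki", sig[:, :2, :2], n)
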