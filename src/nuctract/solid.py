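"""Homogeneous incompressible elastic-solid model.

The interior deformation is extrapolated linearly along radial spokes from
the boundary displacement down to zero at the centroid.  Strain is evaluated
on the induced polar mesh with finite differences (periodic central
differences in the angular direction; the radial direction is exact because
the interpolation is linear), closed in z by incompressibility
``ε_zz = −(ε_xx + ε_yy)``, and converted to stress, energy density and
surface traction.

A consequence of the linear radial rule is that the displacement gradient —
hence strain, stress and energy density — is constant along each spoke; the
total energy therefore reduces to a boundary sum, which is what the fast
path used by the annealer evaluates.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .contour import Contour
from .elasticity import (
    ElasticParams,
    PointMapping,
    StrainField,
    StressField,
    TractionProfile,
    energy_density,
    quadratic_factor,
    stress_from_strain,
    traction,
)
from .errors import MeshError
from .geometry import FrameField, centroid, frames

__all__ = ["SolidModel", "interior_deformation"]

HeightFn = Callable[[np.ndarray], np.ndarray]


def interior_deformation(mapping: PointMapping, radial_fraction: float) -> np.ndarray:
    """Displacement a fraction of the way along each spoke: u(ρ) = ρ·u_boundary.

    ``radial_fraction`` 0 is the centroid (zero deformation by construction),
    1 is the boundary.
    """
    if not 0.0 <= radial_fraction <= 1.0:
        raise ValueError(f"radial_fraction must be in [0, 1], got {radial_fraction}")
    return radial_fraction * mapping.u


def _angular_gradient(f: np.ndarray, dtheta: float, axis: int) -> np.ndarray:
    """Periodic central difference along the angular mesh axis."""
    return (np.roll(f, -1, axis=axis) - np.roll(f, 1, axis=axis)) / (2.0 * dtheta)


class SolidModel:
    """Strain/stress/traction of the solid nucleus on a polar mesh.

    Parameters
    ----------
    params:
        Elastic parameters; ``params.strain_convention`` selects the
        quadratic term of the strain.
    n_rings:
        Number of radial rings of the evaluation mesh (>= 3).
    height:
        Out-of-plane channel height (μm) used in volume integrals; a scalar
        or a callable mapping boundary x positions to heights.
    """

    name = "solid"

    def __init__(self, params: ElasticParams | None = None, n_rings: int = 20,
                 height: float | HeightFn = 1.0):
        self.params = params if params is not None else ElasticParams()
        if n_rings < 3:
            raise MeshError(f"polar mesh needs >= 3 radial rings, got {n_rings}")
        self.n_rings = n_rings
        self.height = height

    # -- mesh construction ------------------------------------------------

    def _centred(self, mapping: PointMapping) -> tuple[np.ndarray, np.ndarray]:
        c = centroid(mapping.initial)
        return mapping.initial.points - c, mapping.u

    def mesh(self, mapping: PointMapping) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rho, X, U): ring fractions, mesh positions, mesh displacements."""
        p, u = self._centred(mapping)
        rho = np.linspace(1.0 / self.n_rings, 1.0, self.n_rings)
        X = rho[:, None, None] * p[None, :, :]
        U = rho[:, None, None] * u[None, :, :]
        return rho, X, U

    def displacement_gradient(self, mapping: PointMapping) -> np.ndarray:
        """∂u_i/∂x_j on the polar mesh, shape (n_rings, N, 2, 2)."""
        rho, X, U = self.mesh(mapping)
        n = X.shape[1]
        dtheta = 2.0 * np.pi / n

        dX = np.empty(X.shape + (2,))
        dU = np.empty(U.shape + (2,))
        dX[..., 0] = np.gradient(X, rho, axis=0)
        dU[..., 0] = np.gradient(U, rho, axis=0)
        dX[..., 1] = _angular_gradient(X, dtheta, axis=1)
        dU[..., 1] = _angular_gradient(U, dtheta, axis=1)

        # g·J = dU with J[..., i, a] = ∂X_i/∂a  =>  Jᵀ gᵀ = dUᵀ
        g = np.linalg.solve(np.swapaxes(dX, -1, -2), np.swapaxes(dU, -1, -2))
        return np.swapaxes(g, -1, -2)

    # -- fields -----------------------------------------------------------

    def strain(self, mapping: PointMapping) -> StrainField:
        """Strain tensors on the mesh; z closed by incompressibility."""
        g = self.displacement_gradient(mapping)
        return StrainField(_strain_tensors(g, self.params.strain_convention))

    def stress(self, strain: StrainField) -> StressField:
        return stress_from_strain(strain, self.params)

    def boundary_strain(self, mapping: PointMapping) -> StrainField:
        return StrainField(self.strain(mapping).tensors[-1])

    def _heights(self, x: np.ndarray) -> np.ndarray:
        if callable(self.height):
            return np.asarray(self.height(x), dtype=float)
        return np.full_like(x, float(self.height))

    def total_energy(self, mapping: PointMapping) -> float:
        """∫ f dV over the nucleus (Pa·μm³; 1 Pa·μm³ = 1e-18 J).

        Uses the edge-midpoint quadrature of :meth:`bind_energy`, which is
        stiff against the alternating (checkerboard) mode that node-centred
        central differences cannot see.
        """
        return self.bind_energy(mapping.initial)(mapping.target.points)

    def traction_profile(self, mapping: PointMapping,
                         frame_field: FrameField | None = None) -> TractionProfile:
        """Surface traction t = σ·n̂ and energy density along the boundary."""
        fr = frame_field if frame_field is not None else frames(mapping.initial)
        if len(fr) != len(mapping):
            raise MeshError("frame field and mapping lengths differ")
        eps_b = self.boundary_strain(mapping)
        sig_b = self.stress(eps_b)
        t = traction(sig_b, fr)
        f = energy_density(eps_b, sig_b)
        return TractionProfile(
            s1=fr.s1, points=mapping.initial.points, traction_vec=t,
            energy=f, model=self.name,
        )

    # -- fast path for the annealer --------------------------------------

    def bind_energy(self, initial: Contour):
        """Precompute initial-contour geometry; return E(target_points).

        Exploits the spoke constancy of the energy density: the volume
        integral reduces to a boundary sum over edge-midpoint wedges, with
        triangle areas as weights (they sum exactly to the polygon area).
        The angular derivative is a forward (edge) difference so alternating
        point redistributions carry their true energy cost — node-centred
        central differences are blind to that mode and would let the
        annealer exploit it.
        """
        c = centroid(initial)
        p = initial.points - c
        n = len(p)
        dtheta = 2.0 * np.pi / n
        pn = np.roll(p, -1, axis=0)
        pe = 0.5 * (p + pn)                       # edge midpoints
        dpe = (pn - p) / dtheta                   # forward angular derivative
        d = pe[:, 0] * dpe[:, 1] - pe[:, 1] * dpe[:, 0]
        if np.any(d == 0.0):
            raise MeshError("degenerate spoke Jacobian on the initial contour")
        wedge = 0.5 * (p[:, 0] * pn[:, 1] - p[:, 1] * pn[:, 0])
        x_edge = 0.5 * (initial.points[:, 0] + np.roll(initial.points[:, 0], -1))
        weights = wedge * self._heights(x_edge)
        q = quadratic_factor(self.params.strain_convention)
        # strain is trace-free after the z-closure, so Hooke's law reduces to
        # σ = E/(1+ν) ε for every ν (= 2E/3 at ν = 0.5)
        modulus = self.params.E / (1.0 + self.params.nu)
        init_pts = initial.points

        def energy(target_points: np.ndarray) -> float:
            u = target_points - init_pts
            un = np.roll(u, -1, axis=0)
            ue = 0.5 * (u + un)
            due = (un - u) / dtheta
            # g_ij on each edge: same chain rule as the mesh route
            g = np.empty((n, 2, 2))
            g[..., 0] = (ue * dpe[:, 1:2] - due * pe[:, 1:2]) / d[:, None]
            g[..., 1] = (-ue * dpe[:, 0:1] + due * pe[:, 0:1]) / d[:, None]
            e2 = 0.5 * (g + np.swapaxes(g, 1, 2)
                        + q * np.einsum("kli,klj->kij", g, g))
            ezz = -(e2[:, 0, 0] + e2[:, 1, 1])
            # f = ½ σ:ε with σ = E/(1+ν) ε on trace-free strain
            ee = np.einsum("kij,kij->k", e2, e2) + ezz**2
            f = 0.5 * modulus * ee
            return float(np.sum(f * weights))

        return energy


def _strain_tensors(g: np.ndarray, convention: str) -> np.ndarray:
    """3×3 strain tensors from in-plane displacement gradients (..., 2, 2)."""
    q = quadratic_factor(convention)
    e2 = 0.5 * (g + np.swapaxes(g, -1, -2) + q * np.einsum("...ki,...kj->...ij", g, g))
    out = np.zeros(g.shape[:-2] + (3, 3))
    out[..., :2, :2] = e2
    out[..., 2, 2] = -(e2[..., 0, 0] + e2[..., 1, 1])
    return out


def _sector_areas(p: np.ndarray) -> np.ndarray:
    """Per-spoke sector areas; they sum exactly to the shoelace polygon area."""
    pn = np.roll(p, -1, axis=0)
    pp = np.roll(p, 1, axis=0)
    return 0.25 * (p[:, 0] * (pn[:, 1] - pp[:, 1]) - p[:, 1] * (pn[:, 0] - pp[:, 0]))
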