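"""Thin elastic shell model of the nucleus outline.

The interior offers no resistance; only tangential surface strains are
non-zero (constant thickness, normals remain normal).  Displacements are
differentiated along the boundary in Cartesian components — which carries
the curvature coupling of the rotating frame implicitly and exactly — and
projected onto the local (n̂, ŝ₁) basis.  The out-of-plane tangential strain
is closed by incompressibility, ``ε_s2s2 = −ε_s1s1`` (trace-free, consistent
with constant shell thickness and constant enclosed volume).

Because the strain tensor is diagonal and trace-free in the surface basis,
the normal-normal stress vanishes and the reported traction is purely
tangential — force per unit area transmitted across the shell cross-section,
``t = σ_s1s1 ŝ₁`` in Pa at the mid-surface.  The shell thickness h enters
only the total-energy integral, never the reported traction.
"""

from __future__ import annotations

import numpy as np

from .contour import Contour
from .elasticity import (
    ElasticParams,
    PointMapping,
    StrainField,
    StressField,
    TractionProfile,
    quadratic_factor,
    stress_from_strain,
)
from .errors import MeshError
from .geometry import FrameField, frames

__all__ = ["ShellModel", "surface_strain_closure"]


def surface_strain_closure(eps_s1s1: np.ndarray) -> np.ndarray:
    """Out-of-plane tangential strain from incompressibility: ε_s2s2 = −ε_s1s1.

    Isolated so a uniaxial variant (ε_s2s2 = 0) is a one-line swap.
    """
    return -eps_s1s1


class ShellModel:
    """Love–Kirchhoff surface strain, stress and traction on an outline."""

    name = "shell"

    def __init__(self, params: ElasticParams | None = None):
        self.params = params if params is not None else ElasticParams()

    # -- strain -----------------------------------------------------------

    def _tangential_derivative(self, mapping: PointMapping) -> np.ndarray:
        """du/ds1 of the Cartesian displacement along the initial outline.

        Periodic central differences with the true (non-uniform) chord
        spacing; exactly zero for a rigid translation.
        """
        p = mapping.initial.points
        u = mapping.u
        ds = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)  # |p_{k+1} - p_k|
        span = (np.roll(ds, 1) + ds)[:, None]
        return (np.roll(u, -1, axis=0) - np.roll(u, 1, axis=0)) / span

    def surface_strain(self, mapping: PointMapping,
                       frame_field: FrameField | None = None) -> StrainField:
        """Strain tensors in the (n, s1, s2) basis, shape (N, 3, 3)."""
        fr = frame_field if frame_field is not None else frames(mapping.initial)
        if len(fr) != len(mapping):
            raise MeshError("frame field and mapping lengths differ")
        a = self._tangential_derivative(mapping)
        a_n = np.einsum("ij,ij->i", a, fr.normal)
        a_s1 = np.einsum("ij,ij->i", a, fr.tangent)
        q = quadratic_factor(self.params.strain_convention)
        e11 = a_s1 + 0.5 * q * (a_n**2 + a_s1**2)
        out = np.zeros((len(e11), 3, 3))
        out[:, 1, 1] = e11
        out[:, 2, 2] = surface_strain_closure(e11)
        return StrainField(out, basis="surface")

    def stress(self, strain: StrainField) -> StressField:
        return stress_from_strain(strain, self.params)

    # -- traction ---------------------------------------------------------

    def traction_profile(self, mapping: PointMapping,
                         frame_field: FrameField | None = None) -> TractionProfile:
        """Tangential surface traction t = σ_s1s1 ŝ₁ (Pa) plus f = ½ σ:ε."""
        fr = frame_field if frame_field is not None else frames(mapping.initial)
        eps = self.surface_strain(mapping, fr)
        sig = self.stress(eps)
        s11 = sig.tensors[:, 1, 1]
        t = s11[:, None] * fr.tangent
        f = s11 * eps.tensors[:, 1, 1]  # ½(σ11 ε11 + σ22 ε22) with σ22 = −σ11
        return TractionProfile(
            s1=fr.s1, points=mapping.initial.points, traction_vec=t,
            energy=f, model=self.name,
        )

    def shell_traction(self, strain: StrainField, frame_field: FrameField) -> np.ndarray:
        """Traction vectors from a precomputed surface strain field."""
        sig = self.stress(strain)
        if len(sig.tensors) != len(frame_field):
            raise MeshError("strain field and frame field lengths differ")
        return sig.tensors[:, 1, 1, None] * frame_field.tangent

    # -- energy -----------------------------------------------------------

    def total_energy(self, mapping: PointMapping) -> float:
        """∮ f h ds1 over the outline (Pa·μm³ per unit out-of-plane depth).

        Uses the per-segment (edge) quadrature of :meth:`bind_energy`.
        """
        return self.bind_energy(mapping.initial)(mapping.target.points)

    # -- fast path for the annealer --------------------------------------

    def bind_energy(self, initial: Contour):
        """Precompute initial-outline geometry; return E(target_points).

        Strain is evaluated per boundary segment (forward differences along
        the outline) so alternating point redistributions carry their true
        energy cost; node-centred central differences would be blind to
        that mode.
        """
        p = initial.points
        edge = np.roll(p, -1, axis=0) - p
        ds = np.linalg.norm(edge, axis=1)
        tan = edge / ds[:, None]
        nrm = np.column_stack([tan[:, 1], -tan[:, 0]])
        q = quadratic_factor(self.params.strain_convention)
        modulus = self.params.E / (1.0 + self.params.nu)
        h = self.params.h

        def energy(target_points: np.ndarray) -> float:
            u = target_points - p
            a = (np.roll(u, -1, axis=0) - u) / ds[:, None]  # du/ds1 per segment
            a_n = a[:, 0] * nrm[:, 0] + a[:, 1] * nrm[:, 1]
            a_s1 = a[:, 0] * tan[:, 0] + a[:, 1] * tan[:, 1]
            e11 = a_s1 + 0.5 * q * (a_n**2 + a_s1**2)
            f = modulus * e11**2  # σ11 ε11 + σ22 ε22 contracted, halved
            return float(np.sum(f * ds) * h)

        return energy
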