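"""Metropolis simulated annealing for boundary correspondence.

Finds the mapping between an initial and a target outline that minimizes
the deformation free energy of the chosen mechanical model.  Starting from
the equal-angle correspondence, one randomly chosen mapped point at a time
is slid a fixed fraction of the way toward one of its two neighbours;
downhill moves are always kept, uphill moves with probability exp(−ΔE/T)
under a geometric cooling schedule.  The initial temperature is calibrated
so that a configured fraction of proposals (default 20%) is accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour import Contour
from .elasticity import PointMapping
from .errors import AnnealError
from .geometry import centroid, remesh_by_angle

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealConfig",
    "AnnealResult",
    "initial_mapping",
    "propose_move",
    "metropolis_accept",
    "calibrate_temperature",
    "anneal",
]


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule parameters (kB is absorbed into T)."""

    seed: int = 0
    initial_acceptance: float = 0.2
    cooling_factor: float = 0.95
    sweeps_max: int = 500
    stall_sweeps: int = 25
    move_fraction: float = 0.1
    temperature: float | None = None  # None => calibrate from initial_acceptance
    n_points: int | None = None       # None => target point count
    # keep mapped points on the target outline; without it, chord moves let a
    # convex correspondence drift irreversibly inward off the outline
    reproject: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.move_fraction < 1.0:
            raise AnnealError("move_fraction must be in (0, 1)")
        if not 0.0 < self.cooling_factor < 1.0:
            raise AnnealError("cooling_factor must be in (0, 1)")
        if not 0.0 < self.initial_acceptance < 1.0:
            raise AnnealError("initial_acceptance must be in (0, 1)")


@dataclass(frozen=True)
class AnnealResult:
    mapping: PointMapping
    energy: float
    trace: pd.DataFrame = field(repr=False)
    temperature0: float = 0.0


def initial_mapping(initial: Contour, target: Contour, n: int | None = None) -> PointMapping:
    """Equal-angle correspondence: remesh both outlines about their centroids.

    Both contours are resampled to the target's point count (or ``n``) at
    the same equally spaced angles; point k maps to point k.
    """
    if n is None:
        n = len(target)
    ri = remesh_by_angle(initial, n, origin=centroid(initial))
    rt = remesh_by_angle(target, n, origin=centroid(target))
    return PointMapping(ri, rt)


def propose_move(points: np.ndarray, rng: np.random.Generator,
                 move_fraction: float = 0.1) -> tuple[int, np.ndarray]:
    """Pick a random point and slide it toward a random neighbour.

    Returns the point index and its new position: ``move_fraction`` of the
    chord toward the chosen (periodic) neighbour.  A point coincident with
    its neighbour yields a no-op move.
    """
    n = len(points)
    k = int(rng.integers(n))
    step = 1 if rng.integers(2) else -1
    neighbour = points[(k + step) % n]
    new = points[k] + move_fraction * (neighbour - points[k])
    return k, new


def order_preserved(points: np.ndarray, k: int, new_point: np.ndarray,
                    origin: np.ndarray) -> bool:
    """Check the moved point keeps its cyclic angular slot about ``origin``."""
    n = len(points)
    a = points[(k - 1) % n] - origin
    b = new_point - origin
    c = points[(k + 1) % n] - origin
    return (a[0] * b[1] - a[1] * b[0] >= 0.0) and (b[0] * c[1] - b[1] * c[0] >= 0.0)


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Accept downhill moves; uphill with probability exp(−ΔE/T)."""
    if T <= 0.0:
        raise AnnealError(f"temperature must be positive, got {T}")
    if dE <= 0.0:
        return True
    return np.exp(-dE / T) > rng.random()


def calibrate_temperature(energy_fn, mapping: PointMapping,
                          rng: np.random.Generator,
                          target_acceptance: float = 0.2,
                          n_samples: int = 1000,
                          move_fraction: float = 0.1,
                          t_bounds: tuple[float, float] = (1e-12, 1e12)) -> float:
    """Initial temperature giving the requested proposal acceptance rate.

    Samples ``n_samples`` proposals from the initial mapping and bisects T
    (in log space) until the expected Metropolis acceptance over the sample
    matches ``target_acceptance``.  If acceptance already exceeds the target
    at the coldest probed temperature (downhill-dominated sample), that
    temperature is returned with a warning.
    """
    n_samples = max(n_samples, 500)
    pts = mapping.target.points
    e0 = energy_fn(pts)
    dEs = np.empty(n_samples)
    for i in range(n_samples):
        k, new = propose_move(pts, rng, move_fraction)
        cand = pts.copy()
        cand[k] = new
        dEs[i] = energy_fn(cand) - e0

    uphill = dEs[dEs > 0.0]

    def acceptance(T: float) -> float:
        p = np.where(dEs <= 0.0, 1.0, np.exp(-np.maximum(dEs, 0.0) / T))
        return float(np.mean(p))

    lo, hi = t_bounds
    if uphill.size == 0:
        warnings.warn(
            "all sampled proposals are downhill; returning the smallest "
            "probed temperature", stacklevel=2,
        )
        return lo
    if acceptance(lo) >= target_acceptance:
        # the downhill fraction alone exceeds the target, so no temperature
        # can reach it overall; calibrate on the uphill moves instead so the
        # schedule still starts with a meaningful energy scale
        logger.info(
            "downhill fraction %.2f >= target %.2f; calibrating on uphill "
            "acceptance", 1.0 - uphill.size / n_samples, target_acceptance,
        )
        dEs = uphill
    if acceptance(hi) <= target_acceptance:
        return hi
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if acceptance(mid) < target_acceptance:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-12:
            break
    return float(np.sqrt(lo * hi))


def anneal(initial: Contour, target: Contour, model, config: AnnealConfig,
           rng: np.random.Generator | None = None) -> AnnealResult:
    """Minimize the model deformation energy over boundary correspondences.

    ``model`` must expose ``bind_energy(initial_contour) -> E(target_points)``
    (see :class:`~nuctract.solid.SolidModel` / :class:`~nuctract.shell.ShellModel`).
    One sweep = N proposals; T is multiplied by ``cooling_factor`` each
    sweep; terminates after ``sweeps_max`` sweeps or once the best energy has
    improved by less than a relative 1e-6 for ``stall_sweeps`` consecutive
    sweeps.  Fully reproducible given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mapping = initial_mapping(initial, target, config.n_points)
    energy_fn = model.bind_energy(mapping.initial)
    origin = centroid(mapping.target)
    tgt_contour = mapping.target

    pts = mapping.target.points.copy()
    e_cur = energy_fn(pts)
    if not np.isfinite(e_cur):
        raise AnnealError("non-finite energy for the initial mapping")
    best_pts = pts.copy()
    e_best = e_cur

    if config.temperature is not None:
        T = float(config.temperature)
    else:
        T = calibrate_temperature(
            energy_fn, mapping, rng,
            target_acceptance=config.initial_acceptance,
            move_fraction=config.move_fraction,
        )
    T0 = T

    n = len(pts)
    rows = []
    stall = 0
    for sweep in range(config.sweeps_max):
        e_best_before = e_best
        accepted = 0
        for _ in range(n):
            k, new = propose_move(pts, rng, config.move_fraction)
            if not order_preserved(pts, k, new, origin):
                continue  # order-violating proposals rejected outright
            if config.reproject:
                new = _project_onto(tgt_contour.points, new)
            old = pts[k].copy()
            pts[k] = new
            e_new = energy_fn(pts)
            if not np.isfinite(e_new):
                raise AnnealError(f"non-finite energy after moving point {k}")
            if metropolis_accept(e_new - e_cur, T, rng):
                e_cur = e_new
                accepted += 1
                if e_cur < e_best:
                    e_best = e_cur
                    best_pts = pts.copy()
            else:
                pts[k] = old
        if e_best > e_best_before + 1e-15:
            raise AnnealError("best energy increased — bookkeeping bug")
        rows.append(
            (sweep, T, e_cur, e_best, accepted / n)
        )
        rel_gain = (e_best_before - e_best) / max(abs(e_best_before), 1e-300)
        stall = stall + 1 if rel_gain < 1e-6 else 0
        if stall >= config.stall_sweeps:
            break
        T *= config.cooling_factor

    trace = pd.DataFrame(
        rows, columns=["sweep", "temperature", "current_energy",
                       "best_energy", "acceptance_rate"],
    )
    best = PointMapping(mapping.initial, Contour(best_pts))
    return AnnealResult(mapping=best, energy=e_best, trace=trace, temperature0=T0)


def _project_onto(polyline: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Closest point on the closed polyline (optional move re-projection)."""
    a = polyline
    b = np.roll(polyline, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / np.where(denom == 0, 1, denom), 0, 1)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - point, proj - point)
    return proj[int(np.argmin(d2))]
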