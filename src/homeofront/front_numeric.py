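"""Brute-force dominance oracle and evolutionary Pareto simulation.

These numerical routes serve both as standalone methods and as the
validation oracle for the analytic front: a dominance filter over point
clouds (strict-in-both by default), an exact non-dominated-subset filter
over parameter grids, and the filter-and-perturb evolutionary simulation
in which a population is repeatedly dominance-filtered, perturbed by
shrinking isotropic noise, and re-evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core_model import StimulusProtocol
from .performance import PerformanceSpec, cost_fields

__all__ = [
    "Population",
    "dominance_filter",
    "dominance_mask",
    "evolve_population",
    "grid_front",
    "hausdorff_distance",
]


@dataclass
class Population:
    """A set of parameter points with their costs and provenance."""

    points: np.ndarray            # (n, 2) columns (kc, y0)
    J_eff: np.ndarray
    J_econ: np.ndarray
    generation: int = 0
    seed: Optional[int] = None
    noise_schedule: tuple = ()
    dist_to_front: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


def _strict_mask(J1: np.ndarray, J2: np.ndarray) -> np.ndarray:
    """Non-dominated mask under strict-in-both dominance, O(n log n).

    A point is dominated iff some point is strictly better in *both*
    costs.  Sort by J1; a point is dominated iff the running minimum of
    J2 over strictly smaller J1 beats its own J2.
    """
    order = np.lexsort((J2, J1))
    J1s, J2s = J1[order], J2[order]
    uniq, idx = np.unique(J1s, return_index=True)
    prefix = np.minimum.accumulate(np.minimum.reduceat(J2s, idx))
    group = np.searchsorted(uniq, J1s)
    best_smaller = np.where(group > 0, prefix[np.maximum(group - 1, 0)], np.inf)
    keep = ~(best_smaller < J2s)
    out = np.zeros(len(J1), dtype=bool)
    out[order] = keep
    return out


def _weak_mask(J1: np.ndarray, J2: np.ndarray) -> np.ndarray:
    """Non-dominated mask under weak dominance.

    q dominates p iff q <= p in both costs and q < p in at least one.
    """
    order = np.lexsort((J2, J1))
    J1s, J2s = J1[order], J2[order]
    uniq, idx = np.unique(J1s, return_index=True)
    grp_min = np.minimum.reduceat(J2s, idx)
    prefix = np.minimum.accumulate(grp_min)
    group = np.searchsorted(uniq, J1s)
    best_smaller = np.where(group > 0, prefix[np.maximum(group - 1, 0)], np.inf)
    # Dominated by a strictly-smaller-J1 point with J2 <= own J2 ...
    dominated = best_smaller <= J2s
    # ... or by an equal-J1 point with strictly smaller J2.
    dominated |= grp_min[group] < J2s
    out = np.zeros(len(J1), dtype=bool)
    out[order] = ~dominated
    return out


def dominance_mask(J_eff: np.ndarray, J_econ: np.ndarray,
                   strictness: str = "strict") -> np.ndarray:
    """Boolean mask of non-dominated points (costs: lower is better)."""
    J1 = np.asarray(J_eff, dtype=float)
    J2 = np.asarray(J_econ, dtype=float)
    if strictness == "strict":
        return _strict_mask(J1, J2)
    if strictness == "weak":
        return _weak_mask(J1, J2)
    raise ValueError(f"unknown strictness {strictness!r}")


def dominance_filter(population: Population,
                     strictness: str = "strict") -> Population:
    """Remove every dominated point from the population."""
    keep = dominance_mask(population.J_eff, population.J_econ, strictness)
    return Population(
        points=population.points[keep],
        J_eff=population.J_eff[keep],
        J_econ=population.J_econ[keep],
        generation=population.generation,
        seed=population.seed,
        noise_schedule=population.noise_schedule,
        meta=dict(population.meta),
    )


def _costs_of_points(points: np.ndarray, protocol: StimulusProtocol,
                     spec: PerformanceSpec):
    if not spec.quadratic:
        raise NotImplementedError("population costs require n = m = 2")
    kc, y0 = points[:, 0], points[:, 1]
    with np.errstate(divide="ignore"):
        k = np.where(kc == 1.0, np.inf, kc / (1.0 - kc))
    return cost_fields(k, y0, protocol)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    x = np.mod(x - lo, 2.0 * span)
    return lo + np.where(x > span, 2.0 * span - x, x)


def evolve_population(
    box: tuple[tuple[float, float], tuple[float, float]],
    n: int,
    iterations: int,
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    noise_start: float = 0.05,
    noise_end: float = 0.001,
    seed: int = 0,
    reference_front: Optional[np.ndarray] = None,
    strictness: str = "strict",
) -> Population:
    """Filter-and-perturb evolutionary Pareto simulation.

    A population of ``n`` points uniform in ``box`` (``(kc_lo, kc_hi),
    (y0_lo, y0_hi)``) is dominance-filtered; survivors are resampled to
    ``n``, perturbed by isotropic Gaussian noise (amplitude a fraction of
    the box size, decaying geometrically from ``noise_start`` to
    ``noise_end`` over the iterations), reflected at the box boundary,
    re-evaluated, and filtered again.  The final survivor set is returned
    with, when a reference front is supplied, each survivor's Euclidean
    distance to it in ``(kc, y0)`` coordinates.
    """
    spec = spec or PerformanceSpec()
    if n < 2:
        raise ValueError("population size must be >= 2")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    (kc_lo, kc_hi), (y_lo, y_hi) = box
    lo = np.array([kc_lo, y_lo], dtype=float)
    hi = np.array([kc_hi, y_hi], dtype=float)
    pts = rng.uniform(lo, hi, size=(n, 2))
    if iterations > 1 and noise_start > 0:
        decay = (noise_end / noise_start) ** (1.0 / (iterations - 1))
    else:
        decay = 1.0

    survivors = pts
    for it in range(iterations):
        J1, J2 = _costs_of_points(pts, protocol, spec)
        keep = dominance_mask(J1, J2, strictness)
        survivors = pts[keep]
        if it == iterations - 1:
            J1, J2 = J1[keep], J2[keep]
            break
        amp = noise_start * decay**it
        idx = rng.integers(0, len(survivors), n)
        noise = rng.normal(0.0, amp, size=(n, 2)) * (hi - lo)
        pts = _reflect(survivors[idx] + noise, lo, hi)

    pop = Population(
        points=survivors, J_eff=J1, J_econ=J2,
        generation=iterations, seed=seed,
        noise_schedule=(noise_start, noise_end, iterations),
        meta={"box": box, "n": n, "strictness": strictness},
    )
    if reference_front is not None:
        tree = cKDTree(np.asarray(reference_front, dtype=float))
        pop.dist_to_front = tree.query(survivors)[0]
    return pop


def grid_front(
    box: tuple[tuple[float, float], tuple[float, float]],
    resolution: int,
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    refine: int = 1,
    strictness: str = "strict",
) -> Population:
    """Non-dominated subset of a regular ``(kc, y0)`` grid.

    With ``refine == 1`` this is the exact non-dominated subset of the
    grid against itself (deterministic).  With ``refine > 1`` each grid
    cell is instead tested against the cost cloud of a ``refine``-times
    finer grid over the same box: the dominating "lens" of a point at
    distance d off the true front has width O(d**2), so grid-vs-grid
    filtering leaves a band of width O(sqrt(cell)) around the front, and
    a denser candidate pool is needed for the oracle to localize the
    front to a couple of cells.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    spec = spec or PerformanceSpec()
    (kc_lo, kc_hi), (y_lo, y_hi) = box
    kc = np.linspace(kc_lo, kc_hi, resolution)
    y0 = np.linspace(y_lo, y_hi, resolution)
    KC, Y0 = np.meshgrid(kc, y0, indexing="ij")
    pts = np.column_stack([KC.ravel(), Y0.ravel()])
    J1, J2 = _costs_of_points(pts, protocol, spec)

    if refine == 1:
        keep = dominance_mask(J1, J2, strictness)
    else:
        kc_f = np.linspace(kc_lo, kc_hi, resolution * refine)
        y0_f = np.linspace(y_lo, y_hi, resolution * refine)
        KCf, Y0f = np.meshgrid(kc_f, y0_f, indexing="ij")
        cand = np.column_stack([KCf.ravel(), Y0f.ravel()])
        J1c, J2c = _costs_of_points(cand, protocol, spec)
        order = np.argsort(J1c, kind="stable")
        cummin = np.minimum.accumulate(J2c[order])
        pos = np.searchsorted(J1c[order], J1, side="left") - 1
        best = np.where(pos >= 0, cummin[np.maximum(pos, 0)], np.inf)
        keep = ~(best < J2)

    return Population(
        points=pts[keep], J_eff=J1[keep], J_econ=J2[keep],
        meta={"box": box, "resolution": resolution, "refine": refine,
              "cell": ((kc_hi - kc_lo) / (resolution - 1),
                       (y_hi - y_lo) / (resolution - 1))},
    )


def hausdorff_distance(A: np.ndarray, B: np.ndarray,
                       cell: Optional[tuple[float, float]] = None) -> float:
    """Symmetric Hausdorff distance between two point sets.

    If ``cell`` is given, coordinates are measured in grid-cell units
    (each axis divided by its cell size) so the result is "number of
    cells".
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if cell is not None:
        scale = np.asarray(cell, dtype=float)
        A = A / scale
        B = B / scale
    d_ab = cKDTree(B).query(A)[0].max()
    d_ba = cKDTree(A).query(B)[0].max()
    return float(max(d_ab, d_ba))


def write_survivors_csv(pop: Population, path) -> None:
    """Write survivors as ``kc,y0,J_eff,J_econ,dist_to_front`` rows."""
    import csv

    dist = pop.dist_to_front
    if dist is None:
        dist = np.full(len(pop), math.nan)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kc", "y0", "J_eff", "J_econ", "dist_to_front"])
        for i in range(len(pop)):
            writer.writerow([
                f"{pop.points[i, 0]:.12g}", f"{pop.points[i, 1]:.12g}",
                f"{pop.J_eff[i]:.12g}", f"{pop.J_econ[i]:.12g}",
                f"{dist[i]:.12g}",
            ])
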