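"""Analytic Pareto front in parameter space.

The Pareto front of the two quadratic costs is the locus of points where
the cost contours are externally tangent.  For the quadratic case the
gradient-alignment (cross-product) condition

    dJ1/dk * dJ2/dy0 - dJ1/dy0 * dJ2/dk = 0

is linear in ``y0`` and solves in closed form.  With the kernels
``a, b`` of :mod:`homeofront.performance`, ``T = t_amb``, ``s = t_step``,
``D = I1 - I0``:

    y0(k) = [ I0 ((T+s) b' - 2 a a') + D (s b' - 2 a a') ] / (2 a' T)

In the rare-input limit ``T -> inf`` this reduces to the input-step
independent curve

    y0(k) = I0 * b'(k) / (2 a'(k))
          = I0 * (1 - (2k+1) e^{-2k}) / (4 (1 - (k+1) e^{-k}))    (s = 1)

which falls monotonically from the economy end ``(k = 0, y0 = I0)`` to a
plateau ``y0 -> I0 / 4`` as ``k -> inf``.  The global front additionally
contains the infinite-responsiveness edge segment from the plateau down
to the effectiveness archetype ``(kc = 1, y0 = 0)`` — the "jump" to the
archetype — because edge points with ``y0 < I0/4`` are undominated at any
finite window.

Tangency points are classified as externally tangent (locally Pareto
optimal), internally tangent (never optimal), or external-but-dominated
("local Pareto front") via a second-order contact test plus a global
dominance check against a brute-force grid oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .core_model import StimulusProtocol
from .performance import (
    PerformanceSpec,
    _ab,
    _ab_prime,
    cost_fields,
    cost_gradients,
    cost_hessians,
)

__all__ = [
    "ParetoFront",
    "RegimeReport",
    "tangency_locus",
    "tangency_residual",
    "external_tangency_test",
    "front_rare_limit",
    "front_finite_T",
    "find_extrema",
    "find_critical_durations",
    "rare_front_y0",
    "finite_front_y0",
]

CLASS_GLOBAL = "global"
CLASS_LOCAL = "local"
CLASS_TANGENT_DOMINATED = "tangent_dominated"


@dataclass
class ParetoFront:
    """Sampled front in parameter space with per-sample classification.

    ``segment`` distinguishes samples of the tangency curve from the
    infinite-responsiveness edge segment that joins the curve's plateau
    to the effectiveness archetype.
    """

    kc: np.ndarray
    k: np.ndarray
    y0: np.ndarray
    cls: np.ndarray               # one of the CLASS_* strings per sample
    segment: np.ndarray           # 'curve' | 'edge'
    J_eff: np.ndarray
    J_econ: np.ndarray
    I0: float
    t_amb: float                  # math.inf for the rare-input limit
    archetypes: dict = field(default_factory=dict)

    @property
    def global_mask(self) -> np.ndarray:
        return self.cls == CLASS_GLOBAL

    def points(self, segment: Optional[str] = None) -> np.ndarray:
        """(n, 2) array of (kc, y0) samples, optionally one segment."""
        sel = slice(None) if segment is None else (self.segment == segment)
        return np.column_stack([self.kc[sel], self.y0[sel]])

    def n_global_components(self, min_run: int = 2) -> int:
        """Number of disjoint global-front components.

        Samples are walked in order (tangency curve by increasing kc,
        then the edge segment downward from the plateau, which attaches
        at kc = 1); a component is a contiguous run of at least
        ``min_run`` globally optimal samples (single-sample islands are
        classification jitter at run boundaries).  The rare-limit front
        is a single component; at any finite ambient interval the
        unstable region near the effectiveness archetype separates the
        curve from the edge piece.
        """
        mask = self.cls == CLASS_GLOBAL
        edges = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        return int(np.sum((ends - starts) >= min_run))

    def write_csv(self, path: Union[str, Path]) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kc", "k", "y0", "class", "J_eff", "J_econ",
                             "T_amb", "I0"])
            for i in range(len(self.kc)):
                writer.writerow([
                    f"{self.kc[i]:.12g}", f"{self.k[i]:.12g}",
                    f"{self.y0[i]:.12g}", self.cls[i],
                    f"{self.J_eff[i]:.12g}", f"{self.J_econ[i]:.12g}",
                    f"{self.t_amb:.12g}", f"{self.I0:.12g}",
                ])


@dataclass
class RegimeReport:
    """Extremum structure of the two costs at one protocol.

    ``extrema`` holds dicts with keys ``task`` (``'effectiveness'`` /
    ``'economy'``), ``k``, ``y0``, ``kind`` (``'maximum'`` for a
    performance maximum, i.e. a cost minimum, or ``'saddle'``) and
    ``location`` (``'interior'`` or ``'boundary'``).  Critical durations
    are the ``t_amb`` values at which interior stationary points appear.
    """

    critical_durations: dict
    extrema: list
    separatrix: list
    n_front_components: Optional[int] = None

    def n_maxima(self, task: str) -> int:
        return sum(1 for e in self.extrema
                   if e["task"] == task and e["kind"] == "maximum")

    def n_saddles(self, task: str) -> int:
        return sum(1 for e in self.extrema
                   if e["task"] == task and e["kind"] == "saddle")

    def to_json_dict(self) -> dict:
        return {
            "critical_durations": self.critical_durations,
            "extrema": self.extrema,
            "separatrix": [np.asarray(p).tolist() for p in self.separatrix],
            "n_front_components": self.n_front_components,
        }


# ----------------------------------------------------------------------
# Closed-form front curves (quadratic costs).
# ----------------------------------------------------------------------

def rare_front_y0(k, I0: float, t_step: float = 1.0) -> np.ndarray:
    """Rare-input-limit front ``y0(k)``; handles ``k = 0`` and ``inf``."""
    k = np.asarray(k, dtype=float)
    out = np.empty_like(k)
    inf = np.isinf(k)
    out[inf] = I0 / 4.0
    kf = k[~inf]
    apv, bpv = _ab_prime(kf, t_step)
    out[~inf] = I0 * bpv / (2.0 * apv)
    return out


def finite_front_y0(k, protocol: StimulusProtocol) -> np.ndarray:
    """Finite-window tangency curve ``y0(k)`` (linear-in-y0 solution)."""
    if math.isinf(protocol.t_amb):
        raise ValueError("t_amb is infinite; use front_rare_limit")
    k = np.asarray(k, dtype=float)
    s, T = protocol.t_step, protocol.t_amb
    I0, D = protocol.I0, protocol.step_amplitude
    out = np.empty_like(k)
    inf = np.isinf(k)
    out[inf] = (I0 * (T + s) + D * s) / (4.0 * T)
    kf = k[~inf]
    a, _ = _ab(kf, s)
    apv, bpv = _ab_prime(kf, s)
    out[~inf] = (I0 * ((T + s) * bpv - 2.0 * a * apv)
                 + D * (s * bpv - 2.0 * a * apv)) / (2.0 * apv * T)
    return out


def tangency_residual(k, y0, protocol: StimulusProtocol) -> np.ndarray:
    """Normalized gradient cross product; zero on the tangency locus."""
    J1k, J1y, J2k, J2y = cost_gradients(k, y0, protocol)
    cross = J1k * J2y - J1y * J2k
    scale = np.abs(J1k * J2y) + np.abs(J1y * J2k)
    return cross / np.where(scale == 0, 1.0, scale)


def _kc_to_k(kc: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(kc == 1.0, np.inf, kc / (1.0 - kc))


def tangency_locus(
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    n_samples: int = 512,
    polish: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Tangency curve sampled on a compactified ``kc`` grid.

    Returns ``(kc, y0)`` arrays.  For the quadratic case the zero set of
    the gradient-alignment condition is available in closed form; with
    ``polish=True`` each sample is additionally refined by a bracketing
    root find on the cross-product residual, seeded from the previous
    sample (continuation), as a numerical cross-check.
    """
    spec = spec or PerformanceSpec()
    if not spec.quadratic:
        raise NotImplementedError("tangency locus requires n = m = 2")
    kc = np.linspace(0.0, 1.0, n_samples)
    k = _kc_to_k(kc)
    y0 = finite_front_y0(k, protocol)
    if polish:
        span = max(abs(y0).max(), protocol.I0)
        for i in range(1, n_samples - 1):
            ki = np.array([k[i]])
            f = lambda y: float(tangency_residual(ki, np.array([y]), protocol)[0])
            guess = y0[i]
            lo, hi = guess - 0.05 * span, guess + 0.05 * span
            try:
                if f(lo) * f(hi) < 0:
                    y0[i] = brentq(f, lo, hi, xtol=1e-14)
            except ValueError:
                pass  # keep closed-form value; flagged by residual tests
    return kc, y0


def external_tangency_test(
    point: tuple[float, float],
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    rel_tol: float = 1e-7,
) -> str:
    """Classify the contact of the two cost contours at a tangency point.

    Returns ``'external'`` when the touching contours bound locally
    disjoint sublevel sets (the point is locally Pareto optimal),
    ``'internal'`` when one sublevel set locally contains the other, and
    ``'indeterminate'`` for degenerate (zero-curvature) contact.

    The test is the second-order constrained-optimality condition: with
    anti-parallel gradients ``grad J2 = -mu grad J1`` (``mu > 0``), the
    point is externally tangent iff ``t' (H2 + mu H1) t > 0`` for the
    common tangent direction ``t``.  Parallel (same-direction) gradients
    are internal contact outright.
    """
    spec = spec or PerformanceSpec()
    if not spec.quadratic:
        raise NotImplementedError("tangency classification requires n = m = 2")
    k, y0 = point
    kk = np.array([float(k)])
    yy = np.array([float(y0)])
    J1k, J1y, J2k, J2y = (float(g[0]) for g in cost_gradients(kk, yy, protocol))
    g1 = np.array([J1k, J1y])
    g2 = np.array([J2k, J2y])
    n1, n2 = np.linalg.norm(g1), np.linalg.norm(g2)
    if n1 == 0 or n2 == 0:
        return "indeterminate"
    if np.dot(g1, g2) > 0:
        return "internal"
    mu = n2 / n1
    t_hat = np.array([-g1[1], g1[0]]) / n1
    H1, H2 = cost_hessians(kk, yy, protocol)
    H = H2[0] + mu * H1[0]
    q = float(t_hat @ H @ t_hat)
    scale = float(abs(t_hat @ H2[0] @ t_hat) + mu * abs(t_hat @ H1[0] @ t_hat))
    if scale == 0 or abs(q) <= rel_tol * scale:
        return "indeterminate"
    return "external" if q > 0 else "internal"


# ----------------------------------------------------------------------
# Front constructors.
# ----------------------------------------------------------------------

def _edge_segment(I0: float, y_top: float, n: int) -> tuple[np.ndarray, ...]:
    """Vertical kc = 1 segment from the plateau down to the archetype."""
    y = np.linspace(y_top, 0.0, n)
    kc = np.ones(n)
    k = np.full(n, np.inf)
    return kc, k, y


def front_rare_limit(
    I0: float,
    n_samples: int = 512,
    t_step: float = 1.0,
    include_edge: bool = True,
    n_edge: int = 128,
) -> ParetoFront:
    """Closed-form global Pareto front in the rare-input limit.

    The curve connects the economy archetype ``(kc = 0, y0 = I0)`` to the
    plateau ``y0 = I0/4`` at ``kc -> 1`` and is independent of the step
    level ``I1``; the edge segment continues down to the effectiveness
    archetype ``(kc = 1, y0 = 0)``.
    """
    if not (I0 > 0):
        raise ValueError("I0 must be > 0")
    kc = np.linspace(0.0, 1.0, n_samples)
    k = _kc_to_k(kc)
    y0 = rare_front_y0(k, I0, t_step)
    seg = np.full(n_samples, "curve", dtype=object)
    if include_edge:
        ekc, ek, ey = _edge_segment(I0, float(y0[-1]), n_edge)
        kc = np.concatenate([kc, ekc])
        k = np.concatenate([k, ek])
        y0 = np.concatenate([y0, ey])
        seg = np.concatenate([seg, np.full(n_edge, "edge", dtype=object)])
    # Rare-limit costs: the window average is dominated by the ambient
    # steady state, J_eff -> y0^2, J_econ -> (I0 - y0)^2.
    J1 = y0**2
    J2 = (I0 - y0) ** 2
    cls = np.full(len(kc), CLASS_GLOBAL, dtype=object)
    return ParetoFront(
        kc=kc, k=k, y0=y0, cls=cls, segment=seg, J_eff=J1, J_econ=J2,
        I0=I0, t_amb=math.inf,
        archetypes={"economy": (0.0, I0), "effectiveness": (1.0, 0.0)},
    )


def _dominated_against(J1t, J2t, J1c, J2c):
    """Strict-in-both dominance of targets against a candidate pool."""
    order = np.argsort(J1c, kind="stable")
    J1s = J1c[order]
    cummin = np.minimum.accumulate(J2c[order])
    pos = np.searchsorted(J1s, J1t, side="left") - 1
    best = np.where(pos >= 0, cummin[np.maximum(pos, 0)], np.inf)
    return best < J2t


def front_finite_T(
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    n_samples: int = 512,
    oracle_resolution: int = 700,
    include_edge: bool = True,
    with_critical_durations: bool = True,
) -> tuple[ParetoFront, RegimeReport]:
    """Front at a finite ambient interval, with segment classification.

    The closed-form tangency curve is sampled on a compactified grid,
    restricted to the physical region ``y0 >= 0``, and each sample is
    classified in order: tangency (by construction) -> external-contact
    test -> global dominance check against a dense grid oracle.
    Externally tangent but dominated samples form the "local Pareto
    front"; internally tangent samples are never optimal (the separatrix
    segments).  The regime report carries the extremum classification of
    both costs and, optionally, the bisection-located critical durations.
    """
    spec = spec or PerformanceSpec()
    if not spec.quadratic:
        raise NotImplementedError("analytic front requires n = m = 2")
    if math.isinf(protocol.t_amb):
        raise ValueError("t_amb is infinite; use front_rare_limit")
    I0 = protocol.I0
    kc, y0 = tangency_locus(protocol, spec, n_samples=n_samples)
    k = _kc_to_k(kc)
    physical = y0 >= 0.0
    cls = np.full(n_samples, CLASS_TANGENT_DOMINATED, dtype=object)

    # Second-order contact classification.
    external = np.zeros(n_samples, dtype=bool)
    idx_physical = np.nonzero(physical)[0]
    for i in idx_physical:
        verdict = external_tangency_test((k[i], y0[i]), protocol, spec)
        # Indeterminate (measure-zero) contacts fall through to the
        # dominance check, matching the tie-breaking policy.
        external[i] = verdict != "internal"

    # Global dominance oracle on a dense grid over the physical box.
    y_hi = max(1.5 * I0, 1.05 * float(y0[physical].max(initial=I0)))
    kc_g = np.linspace(0.0, 1.0, oracle_resolution)
    y_g = np.linspace(0.0, y_hi, oracle_resolution)
    KC, YG = np.meshgrid(kc_g, y_g, indexing="ij")
    KG = _kc_to_k(KC)
    J1c, J2c = cost_fields(KG, YG, protocol)
    J1t, J2t = cost_fields(k, y0, protocol)
    dominated = _dominated_against(J1t, J2t, J1c.ravel(), J2c.ravel())

    cls[physical & external & ~dominated] = CLASS_GLOBAL
    cls[physical & external & dominated] = CLASS_LOCAL
    cls[~physical] = CLASS_TANGENT_DOMINATED

    seg = np.full(n_samples, "curve", dtype=object)
    kc_all, k_all, y_all = kc, k, y0
    if include_edge:
        ekc, ek, ey = _edge_segment(I0, float(finite_front_y0(np.array([np.inf]),
                                                              protocol)[0]),
                                    max(32, n_samples // 8))
        kc_all = np.concatenate([kc, ekc])
        k_all = np.concatenate([k, ek])
        y_all = np.concatenate([y0, ey])
        eJ1, eJ2 = cost_fields(ek, ey, protocol)
        edom = _dominated_against(eJ1, eJ2, J1c.ravel(), J2c.ravel())
        ecls = np.where(edom, CLASS_LOCAL, CLASS_GLOBAL).astype(object)
        cls = np.concatenate([cls, ecls])
        seg = np.concatenate([seg, np.full(len(ekc), "edge", dtype=object)])

    J1, J2 = cost_fields(k_all, y_all, protocol)
    front = ParetoFront(
        kc=kc_all, k=k_all, y0=y_all, cls=cls, segment=seg,
        J_eff=J1, J_econ=J2, I0=I0, t_amb=protocol.t_amb,
        archetypes={"economy": (0.0, I0), "effectiveness": (1.0, 0.0)},
    )

    report = find_extrema(protocol, spec,
                          with_critical_durations=with_critical_durations)
    report.n_front_components = front.n_global_components()
    # Separatrix: contiguous internally-tangent stretches of the curve.
    sep = []
    mask = (cls[: n_samples] == CLASS_TANGENT_DOMINATED)
    splits = np.nonzero(np.diff(mask.astype(int)))[0] + 1
    for chunk in np.split(np.arange(n_samples), splits):
        if len(chunk) > 1 and mask[chunk[0]]:
            sep.append(np.column_stack([kc[chunk], y0[chunk]]))
    report.separatrix = sep
    return front, report


# ----------------------------------------------------------------------
# Extremum structure and critical durations.
# ----------------------------------------------------------------------

def _stationary_k_conditions(protocol: StimulusProtocol):
    """Return h_eff(k), h_econ(k): interior stationary points are roots.

    Eliminating y0 from ``grad J = 0`` for each cost leaves a scalar
    condition in ``k``:

        effectiveness:  b'/(2a') - a/(T+s) = 0,
                        y0* = -D a / (T+s)
        economy:        b'/(2a') - 1 + (s-a)/(T+s) = 0,
                        y0* = I0 + D (s-a) / (T+s)
    """
    s, T = protocol.t_step, protocol.t_amb

    def h_eff(k):
        a, _ = _ab(k, s)
        apv, bpv = _ab_prime(k, s)
        return bpv / (2.0 * apv) - a / (T + s)

    def h_econ(k):
        a, _ = _ab(k, s)
        apv, bpv = _ab_prime(k, s)
        return bpv / (2.0 * apv) - 1.0 + (s - a) / (T + s)

    return h_eff, h_econ


def _scan_roots(h, k_lo=1e-4, k_hi=1e4, n=3000) -> list[float]:
    kk = np.logspace(math.log10(k_lo), math.log10(k_hi), n)
    vals = h(kk)
    roots = []
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for i in sign_change:
        f = lambda x: float(h(np.array([x]))[0])
        roots.append(brentq(f, kk[i], kk[i + 1], xtol=1e-12, rtol=1e-12))
    return roots


def _classify_stationary(k: float, y0: float, protocol: StimulusProtocol,
                         which: str) -> str:
    H1, H2 = cost_hessians(np.array([k]), np.array([y0]), protocol)
    H = H1[0] if which == "effectiveness" else H2[0]
    det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
    if det < 0:
        return "saddle"
    # J_yy = 2 > 0 always, so det > 0 means a cost minimum, i.e. a
    # performance maximum.
    return "maximum"


def find_extrema(
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    with_critical_durations: bool = False,
) -> RegimeReport:
    """Stationary points of each cost with Hessian classification.

    Interior stationary points are located by a root scan of the reduced
    scalar conditions; boundary extrema of the compactified domain (the
    archetype corners and, below the economy critical duration, the
    infinite-responsiveness edge) are classified from the closed forms.
    Above both critical durations each cost has exactly one performance
    maximum; below its critical duration a cost gains a second maximum
    and a saddle.
    """
    spec = spec or PerformanceSpec()
    if not spec.quadratic:
        raise NotImplementedError("extremum analysis requires n = m = 2")
    s, T = protocol.t_step, protocol.t_amb
    I0, D = protocol.I0, protocol.step_amplitude
    h_eff, h_econ = _stationary_k_conditions(protocol)

    extrema: list[dict] = []
    # Effectiveness boundary maximum: the archetype corner (kc=1, y0=0)
    # is the unconstrained minimum of J_eff.
    extrema.append({"task": "effectiveness", "k": math.inf, "y0": 0.0,
                    "kind": "maximum", "location": "boundary"})
    for k in _scan_roots(h_eff):
        a, _ = _ab(np.array([k]), s)
        y0 = float(-D * a[0] / (T + s))
        kind = _classify_stationary(k, y0, protocol, "effectiveness")
        extrema.append({"task": "effectiveness", "k": k, "y0": y0,
                        "kind": kind, "location": "interior"})

    # Economy boundary maximum: the archetype corner (k=0, y0=I0) is the
    # unconstrained minimum of J_econ.
    extrema.append({"task": "economy", "k": 0.0, "y0": I0,
                    "kind": "maximum", "location": "boundary"})
    # Infinite-responsiveness edge: J_econ has a 1-D minimum at
    # y0 = I0 + D s/(T+s); it is a local minimum of the full field iff
    # dJ2/dk < 0 as k -> inf, i.e. 3/2 < 2 s/(T+s), i.e. T < s/3.
    if T < s / 3.0:
        extrema.append({"task": "economy", "k": math.inf,
                        "y0": I0 + D * s / (T + s),
                        "kind": "maximum", "location": "boundary"})
    for k in _scan_roots(h_econ):
        a, _ = _ab(np.array([k]), s)
        y0 = float(I0 + D * (s - a[0]) / (T + s))
        kind = _classify_stationary(k, y0, protocol, "economy")
        extrema.append({"task": "economy", "k": k, "y0": y0,
                        "kind": kind, "location": "interior"})

    critical = {}
    if with_critical_durations:
        critical = find_critical_durations(protocol, spec)
    return RegimeReport(critical_durations=critical, extrema=extrema,
                        separatrix=[])


def find_critical_durations(
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
    t_lo: float = 1e-3,
    t_hi: Optional[float] = None,
    rel_tol: float = 1e-4,
) -> dict:
    """Critical ambient durations per task, located by bisection.

    For each cost, the critical ``t_amb`` is where interior stationary
    points first appear as the ambient interval shrinks (the count of
    performance maxima changes from one to two).  Returns
    ``{'effectiveness': T_c_eff, 'economy': T_c_econ}`` with ``None`` if
    no transition lies in the bracket.
    """
    spec = spec or PerformanceSpec()
    s = protocol.t_step
    t_hi = t_hi if t_hi is not None else 2.0 * s

    def has_interior(task: str, T: float) -> bool:
        proto = StimulusProtocol(I0=protocol.I0, I1=protocol.I1,
                                 t_amb=T, t_step=s)
        h_eff, h_econ = _stationary_k_conditions(proto)
        h = h_eff if task == "effectiveness" else h_econ
        kk = np.logspace(-4, 4, 3000)
        return bool(np.any(np.diff(np.sign(h(kk))) != 0))

    out = {}
    for task in ("effectiveness", "economy"):
        lo, hi = t_lo, t_hi
        if not has_interior(task, lo) or has_interior(task, hi):
            out[task] = None
            continue
        while (hi - lo) / hi > rel_tol:
            mid = 0.5 * (lo + hi)
            if has_interior(task, mid):
                lo = mid
            else:
                hi = mid
        out[task] = 0.5 * (lo + hi)
    return out
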