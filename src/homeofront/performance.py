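"""Effectiveness and economy performance functionals.

Both tasks are scored as *costs* (lower is better) so that dominance has a
single orientation throughout the package; the increasing-is-better
"performance" of the tradeoff literature is one negation away at the API
boundary.

Over a full cycle (ambient segment of duration ``T = t_amb`` at steady
state, then a step of duration ``s = t_step``) the costs are time averages
of powers of the output and of the internal variable,

    J_eff  = <y(t)^n> ,    J_econ = <z(t)^m> ,

with the quadratic case ``n = m = 2`` in closed form.  Writing
``D = I1 - I0``, ``w = I0 - y0`` and the exponential-integral kernels

    a(k) = (1 - exp(-k s)) / k ,    b(k) = (1 - exp(-2 k s)) / (2 k) ,

the window-integrated (unnormalized) costs are

    W * J_eff  = (T + s) y0**2 + 2 y0 D a + D**2 b
    W * J_econ = (T + s) w**2  + 2 D w (s - a) + D**2 (s - 2a + b)

with ``W = T + s``.  All first and second parameter derivatives used by
the front analysis are analytic, with small-``k`` series guarding the
cancellation-prone regime.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.integrate import quad

from .core_model import CircuitParams, StimulusProtocol

__all__ = [
    "PerformanceSpec",
    "PerformancePoint",
    "effectiveness_cost",
    "economy_cost",
    "cost_pair",
    "cost_fields",
    "cost_gradients",
    "cost_hessians",
    "performance_landscape",
    "parabola_relation_check",
    "write_landscape_csv",
]


@dataclass(frozen=True)
class PerformanceSpec:
    """Integrand exponents and averaging-window convention.

    ``n`` scores the output (effectiveness task), ``m`` the internal
    variable (economy task); ``n = m = 2`` is the default and the only
    case with closed forms.  The averaging window is always the full
    cycle ``t_amb + t_step`` of the protocol, with both endpoints carried
    explicitly by the protocol rather than implied.
    """

    n: float = 2.0
    m: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("integrand exponents must be >= 1")

    @property
    def quadratic(self) -> bool:
        return self.n == 2.0 and self.m == 2.0


@dataclass(frozen=True)
class PerformancePoint:
    """Cost pair for one parameter point (lower is better in both)."""

    J_eff: float
    J_econ: float
    lower_is_better: bool = True


# ----------------------------------------------------------------------
# Exponential-integral kernels and derivatives in k.
#
# phi(k, s) = integral_0^s exp(-k t) dt.  a = phi(., s), b = phi(., 2s)/2.
# Series branches cover |k s| < 1e-4 where the closed forms cancel.
# ----------------------------------------------------------------------

def _phi(k: np.ndarray, s: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.empty_like(k)
    inf = np.isinf(k)
    zero = k == 0.0
    rest = ~(inf | zero)
    out[inf] = 0.0
    out[zero] = s
    kr = k[rest]
    out[rest] = (1.0 - np.exp(-kr * s)) / kr
    return out


def _dphi(k: np.ndarray, s: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.empty_like(k)
    inf = np.isinf(k)
    small = (np.abs(k * s) < 1e-4) & ~inf
    rest = ~(inf | small)
    out[inf] = 0.0
    ks = k[small]
    out[small] = -s**2 / 2 + ks * s**3 / 3 - ks**2 * s**4 / 8 + ks**3 * s**5 / 30
    kr = k[rest]
    out[rest] = ((s * kr + 1.0) * np.exp(-kr * s) - 1.0) / kr**2
    return out


def _d2phi(k: np.ndarray, s: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.empty_like(k)
    inf = np.isinf(k)
    small = (np.abs(k * s) < 1e-3) & ~inf
    rest = ~(inf | small)
    out[inf] = 0.0
    ks = k[small]
    out[small] = s**3 / 3 - ks * s**4 / 4 + ks**2 * s**5 / 10 - ks**3 * s**6 / 36
    kr = k[rest]
    E = np.exp(-kr * s)
    out[rest] = (2.0 - E * (s**2 * kr**2 + 2.0 * s * kr + 2.0)) / kr**3
    return out


def _ab(k, s):
    return _phi(k, s), _phi(k, 2.0 * s) / 2.0


def _ab_prime(k, s):
    return _dphi(k, s), _dphi(k, 2.0 * s) / 2.0


def _ab_second(k, s):
    return _d2phi(k, s), _d2phi(k, 2.0 * s) / 2.0


# ----------------------------------------------------------------------
# Closed-form quadratic costs (vectorized over k and y0).
# ----------------------------------------------------------------------

def cost_fields(k, y0, protocol: StimulusProtocol):
    """Quadratic cost pair ``(J_eff, J_econ)``, vectorized.

    ``k`` may contain ``0`` (economy archetype), finite values, and
    ``inf`` (effectiveness archetype, for which the step transient is
    instantaneous and contributes nothing to either integral beyond the
    internal variable's step-tracking term).
    """
    k = np.asarray(k, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    s = protocol.t_step
    T = protocol.t_amb
    D = protocol.step_amplitude
    w = protocol.I0 - y0
    a, b = _ab(k, s)
    W = T + s
    G1 = W * y0**2 + 2.0 * y0 * D * a + D**2 * b
    G2 = W * w**2 + 2.0 * D * w * (s - a) + D**2 * (s - 2.0 * a + b)
    return G1 / W, G2 / W


def cost_gradients(k, y0, protocol: StimulusProtocol):
    """Analytic gradients ``(dJ1/dk, dJ1/dy0, dJ2/dk, dJ2/dy0)``."""
    k = np.asarray(k, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    s = protocol.t_step
    T = protocol.t_amb
    D = protocol.step_amplitude
    w = protocol.I0 - y0
    a, _ = _ab(k, s)
    apv, bpv = _ab_prime(k, s)
    W = T + s
    J1k = (2.0 * y0 * D * apv + D**2 * bpv) / W
    J1y = (2.0 * W * y0 + 2.0 * D * a) / W
    J2k = (-2.0 * D * w * apv + D**2 * (bpv - 2.0 * apv)) / W
    J2y = -(2.0 * W * w + 2.0 * D * (s - a)) / W
    return J1k, J1y, J2k, J2y


def cost_hessians(k, y0, protocol: StimulusProtocol):
    """Analytic Hessians of the two costs.

    Returns ``(H1, H2)`` with shape ``(..., 2, 2)`` in ``(k, y0)`` order.
    """
    k = np.asarray(k, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    s = protocol.t_step
    T = protocol.t_amb
    D = protocol.step_amplitude
    w = protocol.I0 - y0
    apv, _ = _ab_prime(k, s)
    app, bpp = _ab_second(k, s)
    W = T + s
    J1kk = (2.0 * y0 * D * app + D**2 * bpp) / W
    J1ky = 2.0 * D * apv / W
    J1yy = np.broadcast_to(2.0, np.broadcast(k, y0).shape).astype(float)
    J2kk = (-2.0 * D * w * app + D**2 * (bpp - 2.0 * app)) / W
    J2ky = 2.0 * D * apv / W
    J2yy = J1yy
    H1 = np.stack([np.stack([J1kk, J1ky], axis=-1),
                   np.stack([np.broadcast_to(J1ky, J1kk.shape), J1yy], axis=-1)],
                  axis=-2)
    H2 = np.stack([np.stack([J2kk, J2ky], axis=-1),
                   np.stack([np.broadcast_to(J2ky, J2kk.shape), J2yy], axis=-1)],
                  axis=-2)
    return H1, H2


# ----------------------------------------------------------------------
# Public per-point costs with general exponents.
# ----------------------------------------------------------------------

def _power_cost(params: CircuitParams, protocol: StimulusProtocol,
                exponent: float, which: str) -> float:
    """Window-average of |y|^n or z^m by piecewise adaptive quadrature."""
    s = protocol.t_step
    T = protocol.t_amb
    D = protocol.step_amplitude
    y0 = params.y0
    w = protocol.I0 - y0

    if which == "eff":
        amb_val = abs(y0) ** exponent
        if params.is_infinite():
            step_int = s * abs(y0) ** exponent
        elif params.k == 0.0:
            step_int = s * abs(y0 + D) ** exponent
        else:
            f = lambda t: abs(y0 + D * math.exp(-params.k * t)) ** exponent
            step_int, _ = quad(f, 0.0, s, epsabs=1e-10, epsrel=1e-10, limit=200)
    else:
        amb_val = abs(w) ** exponent
        if params.is_infinite():
            # z tracks the input instantly: z = I1 - y0 during the step.
            step_int = s * abs(w + D) ** exponent
        elif params.k == 0.0:
            step_int = s * abs(w) ** exponent
        else:
            f = lambda t: abs((w + D) - D * math.exp(-params.k * t)) ** exponent
            step_int, _ = quad(f, 0.0, s, epsabs=1e-10, epsrel=1e-10, limit=200)
    return (T * amb_val + step_int) / (T + s)


def effectiveness_cost(
    params: CircuitParams,
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
) -> float:
    """Time-averaged ``|y|^n`` over the full cycle (lower is better).

    Uses the closed form for ``n = 2``; adaptive quadrature otherwise.
    """
    spec = spec or PerformanceSpec()
    if spec.n == 2.0:
        kk = np.array([math.inf if params.is_infinite() else params.k])
        J1, _ = cost_fields(kk, np.array([params.y0]), protocol)
        return float(J1[0])
    return _power_cost(params, protocol, spec.n, "eff")


def economy_cost(
    params: CircuitParams,
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
) -> float:
    """Time-averaged ``z^m`` over the full cycle (lower is better)."""
    spec = spec or PerformanceSpec()
    if spec.m == 2.0:
        kk = np.array([math.inf if params.is_infinite() else params.k])
        _, J2 = cost_fields(kk, np.array([params.y0]), protocol)
        return float(J2[0])
    return _power_cost(params, protocol, spec.m, "econ")


def cost_pair(params: CircuitParams, protocol: StimulusProtocol,
              spec: Optional[PerformanceSpec] = None) -> PerformancePoint:
    return PerformancePoint(
        J_eff=effectiveness_cost(params, protocol, spec),
        J_econ=economy_cost(params, protocol, spec),
    )


def performance_landscape(
    kc_grid: np.ndarray,
    y0_grid: np.ndarray,
    protocol: StimulusProtocol,
    spec: Optional[PerformanceSpec] = None,
) -> dict:
    """Dense cost fields on a ``(kc, y0)`` product grid.

    Returns a dict with 2-D arrays ``J_eff``, ``J_econ`` of shape
    ``(len(kc_grid), len(y0_grid))`` plus the axes, suitable for
    contouring and dominance filtering.
    """
    spec = spec or PerformanceSpec()
    kc = np.asarray(kc_grid, dtype=float)
    y0 = np.asarray(y0_grid, dtype=float)
    if np.any(kc < 0) or np.any(kc > 1):
        raise ValueError("kc grid must lie in [0, 1]")
    if np.any(y0 < 0):
        raise ValueError("y0 grid must be >= 0")
    with np.errstate(divide="ignore"):
        k = np.where(kc == 1.0, np.inf, kc / (1.0 - kc))
    KC, Y0 = np.meshgrid(kc, y0, indexing="ij")
    K = np.broadcast_to(k[:, None], KC.shape)
    if spec.quadratic:
        J1, J2 = cost_fields(K, Y0, protocol)
    else:
        J1 = np.empty(KC.shape)
        J2 = np.empty(KC.shape)
        for i in range(KC.shape[0]):
            for j in range(KC.shape[1]):
                p = CircuitParams(k=float(K[i, j]), y0=float(Y0[i, j]))
                J1[i, j] = effectiveness_cost(p, protocol, spec)
                J2[i, j] = economy_cost(p, protocol, spec)
    return {"kc": kc, "y0": y0, "J_eff": J1, "J_econ": J2}


def parabola_relation_check(
    J_eff: np.ndarray,
    J_econ: np.ndarray,
    I0: float,
) -> np.ndarray:
    """Residual of the performance-space parabola along the rare front.

    In the rare-input limit the front's image in performance space is the
    parabola arc ``sqrt(J_eff) + sqrt(J_econ) = I0``; the residual
    returned is ``sqrt(J_eff) + sqrt(J_econ) - I0`` per point (zero on
    the front, nonzero off it at finite window).
    """
    J_eff = np.asarray(J_eff, dtype=float)
    J_econ = np.asarray(J_econ, dtype=float)
    if np.any(J_eff < 0) or np.any(J_econ < 0):
        raise ValueError("costs must be nonnegative")
    return np.sqrt(J_eff) + np.sqrt(J_econ) - I0


def write_landscape_csv(landscape: dict, path: Union[str, Path]) -> None:
    """Write a landscape as ``kc,y0,J_eff,J_econ`` rows."""
    path = Path(path)
    kc, y0 = landscape["kc"], landscape["y0"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kc", "y0", "J_eff", "J_econ"])
        for i in range(len(kc)):
            for j in range(len(y0)):
                writer.writerow([
                    f"{kc[i]:.12g}", f"{y0[j]:.12g}",
                    f"{landscape['J_eff'][i, j]:.12g}",
                    f"{landscape['J_econ'][i, j]:.12g}",
                ])


def export_contours_json(landscape: dict, levels_eff, levels_econ,
                         path: Union[str, Path]) -> None:
    """Export cost contours as JSON polyline lists (matplotlib backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    KC, Y0 = np.meshgrid(landscape["kc"], landscape["y0"], indexing="ij")
    out = {}
    for name, field, levels in (
        ("J_eff", landscape["J_eff"], levels_eff),
        ("J_econ", landscape["J_econ"], levels_econ),
    ):
        fig, ax = plt.subplots()
        cs = ax.contour(KC, Y0, field, levels=levels)
        polys = []
        for level, segs in zip(cs.levels, cs.allsegs):
            for seg in segs:
                polys.append({"level": float(level),
                              "points": np.asarray(seg).tolist()})
        plt.close(fig)
        out[name] = polys
    with open(path, "w") as fh:
        json.dump(out, fh)
        fh.write("\n")
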