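"""Dynamics of the rescaled integral-feedback circuit and its variants.

In rescaled (dimensionless) coordinates the base model is

    y(t) = u(t) - z(t)                     (algebraic; fast output)
    dz/dt = k * (y(t) - y0)                (integral feedback)

with input ``u`` held at an ambient level ``I0`` for a duration ``t_amb``
(the system sits at steady state there) and then stepped to ``I1`` for a
duration ``t_step``.  The step duration is the time unit (``t_step = 1``
under the default normalization); ``t_amb`` is the free duration varied in
the finite-interval front analysis.

Variants: a feed-forward coupling that shifts the responsiveness by an
input-proportional amount; a sign-flipped "calcium" model in which a rise
in demand depresses the output; and a nonlinear model without timescale
separation in which the output relaxes on a finite timescale and decays by
mass action with the internal variable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CircuitParams",
    "StimulusProtocol",
    "Trajectory",
    "RescalingMap",
    "FeedforwardSpec",
    "NonlinearVariantParams",
    "step_response_closed_form",
    "archetype_response",
    "simulate_ode",
    "calcium_response",
    "rescale",
    "load_run_config",
]

#: Normalization convention: the step (activation) interval is the time
#: unit.  Kept in one place so the convention can be audited.
STEP_DURATION_UNIT = 1.0

# Integrator tolerances: k spans orders of magnitude, so the stiff-capable
# adaptive scheme runs tight.
_RTOL = 1e-9
_ATOL = 1e-12


@dataclass(frozen=True)
class CircuitParams:
    """The two rescaled circuit parameters: a point in parameter space.

    Parameters
    ----------
    k : float
        Responsiveness of the internal variable (dimensionless rate,
        ``>= 0``).  ``math.inf`` is accepted only as the effectiveness
        archetype and is stored compactified (``kc == 1``); arithmetic
        paths must branch on :meth:`is_infinite` rather than multiply by
        infinity.
    y0 : float
        Output set-point (dimensionless output units, ``>= 0``).
    """

    k: float
    y0: float

    def __post_init__(self) -> None:
        if not (self.k >= 0):
            raise ValueError(f"responsiveness k must be >= 0, got {self.k}")
        if not (self.y0 >= 0):
            raise ValueError(f"set-point y0 must be >= 0, got {self.y0}")

    @property
    def kc(self) -> float:
        """Compactified responsiveness ``k / (1 + k)`` in ``[0, 1]``."""
        if math.isinf(self.k):
            return 1.0
        return self.k / (1.0 + self.k)

    @classmethod
    def from_kc(cls, kc: float, y0: float) -> "CircuitParams":
        if not (0.0 <= kc <= 1.0):
            raise ValueError(f"kc must lie in [0, 1], got {kc}")
        k = math.inf if kc == 1.0 else kc / (1.0 - kc)
        return cls(k=k, y0=y0)

    def is_infinite(self) -> bool:
        return math.isinf(self.k)


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-pulse input protocol.

    The input sits at the ambient level ``I0`` for ``t_amb`` (system at
    steady state), then steps to ``I1 >= I0`` for ``t_step``.  The rare
    -input limit is ``t_amb -> inf``.
    """

    I0: float
    I1: float
    t_amb: float
    t_step: float = STEP_DURATION_UNIT

    def __post_init__(self) -> None:
        if not (self.I0 > 0):
            raise ValueError(f"ambient input I0 must be > 0, got {self.I0}")
        if not (self.I1 >= self.I0):
            raise ValueError(f"step input I1 must be >= I0, got {self.I1}")
        if not (self.t_amb > 0) or not (self.t_step > 0):
            raise ValueError("durations t_amb and t_step must be > 0")

    @property
    def step_amplitude(self) -> float:
        return self.I1 - self.I0

    @property
    def window(self) -> float:
        """Full averaging window ``t_amb + t_step``."""
        return self.t_amb + self.t_step

    def input_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant input series on times ``t`` (step at t_amb)."""
        t = np.asarray(t, dtype=float)
        return np.where(t < self.t_amb, self.I0, self.I1)


@dataclass
class Trajectory:
    """Time series of one protocol run: input, internal variable, output."""

    t: np.ndarray
    u: np.ndarray
    z: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.u) == len(self.z) == len(self.y)):
            raise ValueError("t, u, z, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def write_csv(self, path: Union[str, Path]) -> None:
        """Write ``t,u,z,y`` columns plus a ``.json`` parameter sidecar."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "u", "z", "y"])
            for row in zip(self.t, self.u, self.z, self.y):
                writer.writerow([f"{v:.12g}" for v in row])
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(self.meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class FeedforwardSpec:
    """Feed-forward coupling: responsiveness becomes ``k + c_ff * u``.

    ``c_ff = 0`` recovers the base model.  For step inputs the response is
    the base-model response with the responsiveness shifted by the
    input-proportional amount, so the Pareto analysis carries over after
    relabeling ``k``.
    """

    c_ff: float = 0.0


@dataclass(frozen=True)
class NonlinearVariantParams:
    """Nonlinear model without timescale separation.

    The output gets its own relaxation timescale ``tau_y`` and (for
    ``decay='mass_action'``) decays by mass action with the internal
    variable at rate ``k_d``:

        tau_y * dy/dt = u - k_d * z * y
        dz/dt = k * (y - y0)

    ``decay='linear'`` uses ``tau_y * dy/dt = u - z - y``, whose
    ``tau_y -> 0`` limit is the base model.
    """

    k_d: float = 1.0
    tau_y: float = 0.05
    decay: str = "mass_action"

    def __post_init__(self) -> None:
        if self.decay not in ("mass_action", "linear"):
            raise ValueError(f"unknown decay form {self.decay!r}")
        if not (self.tau_y > 0):
            raise ValueError("tau_y must be > 0")
        if not (self.k_d > 0):
            raise ValueError("k_d must be > 0")


@dataclass(frozen=True)
class RescalingMap:
    """Map from raw (dimensional) circuit coefficients to rescaled ones.

    The raw model is

        Y = output_coupling * U - internal_action * Z
        dZ/dt = responsiveness * (Y - set_point)

    Dividing the balance by ``internal_action`` and measuring time in
    units of ``activation_timescale`` (the duration over which the system
    is activated, i.e. the step interval) leaves two parameters:

        k  = internal_action * responsiveness * activation_timescale
        y0 = set_point / internal_action

    Equivalently ``k`` is the activation timescale over the circuit's raw
    response time constant ``1 / (internal_action * responsiveness)``.
    """

    output_coupling: float = 1.0
    internal_action: float = 1.0
    responsiveness: float = 1.0
    set_point: float = 1.0
    activation_timescale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("output_coupling", "internal_action", "responsiveness",
                     "activation_timescale"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (self.set_point >= 0):
            raise ValueError("set_point must be >= 0")


def rescale(raw: RescalingMap) -> tuple[CircuitParams, dict]:
    """Rescale raw coefficients to dimensionless ``(k, y0)``.

    Returns the :class:`CircuitParams` and a dict of unit conversions
    (multiply a raw quantity by the factor to obtain its dimensionless
    counterpart).  ``rescale_invert`` recovers the raw map.
    """
    k = raw.internal_action * raw.responsiveness * raw.activation_timescale
    y0 = raw.set_point / raw.internal_action
    scales = {
        "input_scale": raw.output_coupling / raw.internal_action,
        "output_scale": 1.0 / raw.internal_action,
        "z_scale": 1.0,
        "time_scale": 1.0 / raw.activation_timescale,
    }
    return CircuitParams(k=k, y0=y0), scales


def rescale_invert(params: CircuitParams, scales: dict,
                   activation_timescale: float) -> RescalingMap:
    """Inverse of :func:`rescale` given the recorded unit conversions."""
    internal_action = 1.0 / scales["output_scale"]
    output_coupling = scales["input_scale"] * internal_action
    responsiveness = params.k / (internal_action * activation_timescale)
    set_point = params.y0 * internal_action
    return RescalingMap(
        output_coupling=output_coupling,
        internal_action=internal_action,
        responsiveness=responsiveness,
        set_point=set_point,
        activation_timescale=activation_timescale,
    )


def _grid(protocol: StimulusProtocol, n_amb: int, n_step: int) -> np.ndarray:
    """Time grid covering [0, t_amb) ambient plus [t_amb, window] step."""
    t_a = np.linspace(0.0, protocol.t_amb, n_amb, endpoint=False)
    t_s = np.linspace(protocol.t_amb, protocol.window, n_step)
    return np.concatenate([t_a, t_s])


def step_response_closed_form(
    params: CircuitParams,
    protocol: StimulusProtocol,
    n_amb: int = 64,
    n_step: int = 512,
) -> Trajectory:
    """Exact step response of the base model.

    The internal variable approaches its new steady state exponentially,

        z(tau) = (I1 - y0) - (I1 - I0) * exp(-k * tau),

    while the output jumps to ``y0 + (I1 - I0)`` at the step and decays
    back to the set-point,

        y(tau) = y0 + (I1 - I0) * exp(-k * tau),

    with ``tau`` the time since the step.  The ambient segment
    ``[0, t_amb)`` (steady state) is included so that performance
    integrals can cover the full cycle.

    Raises
    ------
    ValueError
        If ``k == 0`` or ``k`` is infinite; use :func:`archetype_response`
        for the archetypes.
    """
    if params.k == 0 or params.is_infinite():
        raise ValueError(
            "closed form requires finite k > 0; use archetype_response "
            "for k = 0 (economy) or k = inf (effectiveness)"
        )
    t = _grid(protocol, n_amb, n_step)
    u = protocol.input_at(t)
    delta = protocol.step_amplitude
    z_amb = protocol.I0 - params.y0
    tau = np.maximum(t - protocol.t_amb, 0.0)
    decay = np.exp(-params.k * tau)
    in_step = t >= protocol.t_amb
    z = np.where(in_step, (protocol.I1 - params.y0) - delta * decay, z_amb)
    y = u - z
    return Trajectory(t, u, z, y, meta={
        "model": "base_closed_form", "k": params.k, "y0": params.y0,
        "I0": protocol.I0, "I1": protocol.I1,
        "t_amb": protocol.t_amb, "t_step": protocol.t_step,
    })


def archetype_response(
    which: str,
    protocol: StimulusProtocol,
    y0: float = 0.0,
    n_amb: int = 64,
    n_step: int = 512,
) -> Trajectory:
    """Response of a single-task archetype circuit.

    ``which='effectiveness'`` is the infinite-responsiveness limit
    (compactified ``kc = 1``): the output is pinned at the set-point, the
    transient being instantaneous, and the internal variable jumps with
    the input.  ``which='economy'`` is the zero-production limit
    (``k = 0``): the internal variable stays at its ambient value and the
    output tracks the input shift without returning to baseline.
    """
    if which not in ("effectiveness", "economy"):
        raise ValueError(f"unknown archetype {which!r}")
    t = _grid(protocol, n_amb, n_step)
    u = protocol.input_at(t)
    if which == "effectiveness":
        y = np.full_like(t, y0)
        z = u - y
        k = math.inf
    else:
        z = np.full_like(t, protocol.I0 - y0)
        y = u - z
        k = 0.0
    return Trajectory(t, u, z, y, meta={
        "model": f"archetype_{which}", "k": k, "y0": y0,
        "I0": protocol.I0, "I1": protocol.I1,
        "t_amb": protocol.t_amb, "t_step": protocol.t_step,
    })


def _steady_state(params: CircuitParams, u: float,
                  variant: Optional[object]) -> np.ndarray:
    """Pre-step steady state of the state vector for each variant."""
    if variant is None or isinstance(variant, FeedforwardSpec):
        return np.array([u - params.y0])
    if isinstance(variant, NonlinearVariantParams):
        if variant.decay == "linear":
            return np.array([u - params.y0, params.y0])
        if params.y0 <= 0:
            raise ValueError("mass-action variant needs y0 > 0 at steady state")
        return np.array([u / (variant.k_d * params.y0), params.y0])
    raise TypeError(f"unknown variant {type(variant).__name__}")


def _rhs(params: CircuitParams, u: float, variant: Optional[object]):
    k, y0 = params.k, params.y0
    if variant is None:
        return lambda t, s: np.array([k * (u - s[0] - y0)])
    if isinstance(variant, FeedforwardSpec):
        k_eff = k + variant.c_ff * u
        return lambda t, s: np.array([k_eff * (u - s[0] - y0)])
    if isinstance(variant, NonlinearVariantParams):
        if variant.decay == "linear":
            def rhs(t, s):
                z, y = s
                return np.array([k * (y - y0), (u - z - y) / variant.tau_y])
        else:
            kd = variant.k_d

            def rhs(t, s):
                z, y = s
                return np.array([k * (y - y0), (u - kd * z * y) / variant.tau_y])
        return rhs
    raise TypeError(f"unknown variant {type(variant).__name__}")


def _output_from_state(state: np.ndarray, u: np.ndarray,
                       variant: Optional[object]) -> tuple[np.ndarray, np.ndarray]:
    if variant is None or isinstance(variant, FeedforwardSpec):
        z = state[0]
        return z, u - z
    return state[0], state[1]


def simulate_ode(
    params: CircuitParams,
    protocol: StimulusProtocol,
    variant: Optional[Union[FeedforwardSpec, NonlinearVariantParams]] = None,
    n_amb: int = 64,
    n_step: int = 512,
    method: str = "LSODA",
) -> Trajectory:
    """Numerical trajectory of the base model or one of its variants.

    Integrates each constant-input segment separately with a
    stiff-capable adaptive scheme (rtol 1e-9 / atol 1e-12); for the base
    linear variant this agrees with :func:`step_response_closed_form` to
    well under 1e-6 in sup-norm.
    """
    if params.is_infinite():
        raise ValueError("simulate_ode requires finite k; use archetype_response")
    t = _grid(protocol, n_amb, n_step)
    in_step = t >= protocol.t_amb
    t_a, t_s = t[~in_step], t[in_step]

    s0 = _steady_state(params, protocol.I0, variant)
    states = []

    # Ambient segment: already at steady state, but integrate anyway so the
    # variant equations are exercised end to end.
    if len(t_a) > 0:
        sol = solve_ivp(
            _rhs(params, protocol.I0, variant),
            (0.0, protocol.t_amb), s0, t_eval=t_a,
            method=method, rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on ambient segment: {sol.message} "
                f"(k={params.k}, nfev={sol.nfev})"
            )
        states.append(sol.y)
        s_at_step = solve_ivp(
            _rhs(params, protocol.I0, variant),
            (0.0, protocol.t_amb), s0,
            method=method, rtol=_RTOL, atol=_ATOL,
        ).y[:, -1]
    else:
        s_at_step = s0

    sol = solve_ivp(
        _rhs(params, protocol.I1, variant),
        (protocol.t_amb, protocol.window), s_at_step, t_eval=t_s,
        method=method, rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(
            f"integrator failed on step segment: {sol.message} "
            f"(k={params.k}, nfev={sol.nfev})"
        )
    states.append(sol.y)

    state = np.concatenate(states, axis=1)
    u = protocol.input_at(t)
    z, y = _output_from_state(state, u, variant)
    name = "base" if variant is None else type(variant).__name__
    return Trajectory(t, u, z, y, meta={
        "model": f"ode_{name}", "k": params.k, "y0": params.y0,
        "I0": protocol.I0, "I1": protocol.I1,
        "t_amb": protocol.t_amb, "t_step": protocol.t_step,
    })


def calcium_response(
    params: CircuitParams,
    protocol: StimulusProtocol,
    n_amb: int = 64,
    n_step: int = 512,
) -> Trajectory:
    """Exact step response of the sign-flipped (calcium-type) model.

        y = z - u,    dz/dt = -k * (y - y0)

    A rise in demand ``u`` pulls the output below its set-point; the
    internal flux rises and restores it.  The output trajectory is the
    base-model one reflected about the set-point:

        y(tau) = y0 - (I1 - I0) * exp(-k * tau).
    """
    if params.k == 0 or params.is_infinite():
        raise ValueError("calcium closed form requires finite k > 0")
    t = _grid(protocol, n_amb, n_step)
    u = protocol.input_at(t)
    delta = protocol.step_amplitude
    tau = np.maximum(t - protocol.t_amb, 0.0)
    decay = np.exp(-params.k * tau)
    in_step = t >= protocol.t_amb
    z = np.where(in_step, (protocol.I1 + params.y0) - delta * decay,
                 protocol.I0 + params.y0)
    y = z - u
    return Trajectory(t, u, z, y, meta={
        "model": "calcium_closed_form", "k": params.k, "y0": params.y0,
        "I0": protocol.I0, "I1": protocol.I1,
        "t_amb": protocol.t_amb, "t_step": protocol.t_step,
    })


def load_run_config(path: Union[str, Path]) -> dict:
    """Read a YAML/JSON run config.

    Recognized keys: ``k, y0, I0, I1, T_amb, T_step, variant,
    variant_params, grid``.  Unknown keys raise, naming the offender.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    allowed = {"k", "y0", "I0", "I1", "T_amb", "T_step",
               "variant", "variant_params", "grid"}
    for key in cfg:
        if key not in allowed:
            raise ValueError(f"unknown config key: {key!r}")
    return cfg


def config_to_objects(cfg: dict):
    """Build (params, protocol, variant, grid) from a run config dict."""
    params = CircuitParams(k=float(cfg.get("k", 1.0)),
                           y0=float(cfg.get("y0", 0.5)))
    protocol = StimulusProtocol(
        I0=float(cfg.get("I0", 1.0)),
        I1=float(cfg.get("I1", 2.0)),
        t_amb=float(cfg.get("T_amb", 10.0)),
        t_step=float(cfg.get("T_step", STEP_DURATION_UNIT)),
    )
    variant = None
    vname = cfg.get("variant")
    vp = cfg.get("variant_params") or {}
    if vname in (None, "base"):
        variant = None
    elif vname == "feedforward":
        variant = FeedforwardSpec(**vp)
    elif vname == "nonlinear":
        variant = NonlinearVariantParams(**vp)
    elif vname == "calcium":
        variant = "calcium"
    else:
        raise ValueError(f"unknown variant: {vname!r}")
    grid = cfg.get("grid") or {}
    return params, protocol, variant, grid
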