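"""Core FitzHugh-Nagumo model: parameters, vector field, steady state and
fixed points.

The model couples a membrane voltage ``u`` (volts) to a slow recovery
current ``w`` (amperes) under an applied current ``I``::

    C_m du/dt = I - (1/R_I) (u^3 / (3 u_1^2) - u) - w
    tau_k dw/dt = u / R_w - b w

with membrane capacitance ``C_m = tau_m / R_I``.  The cubic term gives a
negative differential resistance for ``|u| < u_1`` -- the built-in firing
mechanism -- while the slow linear recovery branch behaves, in the small
signal limit, as a resistor ``R_a = b R_w`` in series with an inductor
``L = tau_k R_w`` (see :mod:`fhncircuit.impedance`).

All quantities are SI: seconds, volts, amperes, ohms, farads, henries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "ModelParams",
    "State",
    "DerivedParams",
    "Derivatives",
    "NullclineValues",
    "derived_params",
    "rhs",
    "stationary_current",
    "stationary_current_slope",
    "nullclines",
    "fixed_points",
]


class State(NamedTuple):
    """Phase-plane point: membrane voltage ``u`` (V), recovery current ``w`` (A)."""

    u: float
    w: float


class DerivedParams(NamedTuple):
    """Derived parameter set: time-scale ratio, resistance ratio, membrane
    capacitance and recovery inductance."""

    epsilon: float
    r: float
    C_m: float
    L: float


class Derivatives(NamedTuple):
    du_dt: float
    dw_dt: float


class NullclineValues(NamedTuple):
    """Recovery current on each nullcline at a given voltage."""

    w_on_u_nullcline: float
    w_on_w_nullcline: float


@dataclass(frozen=True)
class ModelParams:
    """Independent FitzHugh-Nagumo parameters.

    Parameters
    ----------
    tau_m : float
        Membrane voltage response time, s.
    tau_k : float
        Recovery current response time, s.  Excitable-membrane operation
        corresponds to ``tau_k >> tau_m``.
    R_I : float
        Channel resistor, ohm.
    R_w : float
        Recovery current resistor, ohm.
    b : float
        Dimensionless modulation constant of the recovery current.
    u_1 : float, default 1.0
        Reference voltage, V; sets the width of the negative-resistance
        window ``|u| < u_1``.
    """

    tau_m: float
    tau_k: float
    R_I: float
    R_w: float
    b: float
    u_1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_k", "R_I", "R_w", "b", "u_1"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ParameterError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value!r}")

    # -- derived quantities (pure functions of the six fields) ---------------

    @property
    def epsilon(self) -> float:
        """Ratio of time scales tau_m / tau_k (dimensionless)."""
        return self.tau_m / self.tau_k

    @property
    def r(self) -> float:
        """Ratio of resistances R_I / R_w (dimensionless)."""
        return self.R_I / self.R_w

    @property
    def C_m(self) -> float:
        """Membrane capacitance tau_m / R_I, F."""
        return self.tau_m / self.R_I

    @property
    def L(self) -> float:
        """Recovery-current inductance tau_k * R_w, H."""
        return self.tau_k * self.R_w

    @classmethod
    def from_ratios(
        cls,
        *,
        b: float,
        epsilon: float,
        r: float,
        tau_m: float = 1e-2,
        R_I: float = 0.5,
        u_1: float = 1.0,
    ) -> "ModelParams":
        """Build from the dimensionless ratios (epsilon, r) instead of
        (tau_k, R_w), at fixed (tau_m, R_I).  The round trip is exact."""
        if not (isinstance(epsilon, (int, float)) and epsilon > 0):
            raise ParameterError(f"epsilon must be positive, got {epsilon!r}")
        if not (isinstance(r, (int, float)) and r > 0):
            raise ParameterError(f"r must be positive, got {r!r}")
        return cls(tau_m=tau_m, tau_k=tau_m / epsilon, R_I=R_I, R_w=R_I / r, b=b, u_1=u_1)


def derived_params(p: ModelParams) -> DerivedParams:
    """Return (epsilon, r, C_m, L) for a parameter set."""
    return DerivedParams(epsilon=p.epsilon, r=p.r, C_m=p.C_m, L=p.L)


def rhs(s: State | tuple, I: float, p: ModelParams) -> Derivatives:
    """Instantaneous derivatives (du/dt, dw/dt) at state ``s`` under drive ``I``.

    Both components vanish at every fixed point of the drive; the voltage
    equation is linear in ``I`` with slope ``1/C_m``.
    """
    u, w = s
    du_dt = (I - (u ** 3 / (3.0 * p.u_1 ** 2) - u) / p.R_I - w) / p.C_m
    dw_dt = (u / p.R_w - p.b * w) / p.tau_k
    return Derivatives(du_dt=du_dt, dw_dt=dw_dt)


def stationary_current(u, p: ModelParams):
    """Stationary current-voltage relation I(u) (A).

    ``I(u) = (1/R_I)(u^3/(3 u_1^2) - u) + u/(b R_w)``; odd in ``u``.
    Accepts scalars or arrays.
    """
    u = np.asarray(u, dtype=float)
    out = (u ** 3 / (3.0 * p.u_1 ** 2) - u) / p.R_I + u / (p.b * p.R_w)
    return float(out) if out.ndim == 0 else out


def stationary_current_slope(u, p: ModelParams):
    """dI/du of the stationary curve (S); equals 1/R_dc of the equivalent
    circuit at the same bias.  Vanishes at the saddle-node turning points."""
    u = np.asarray(u, dtype=float)
    out = (u ** 2 / p.u_1 ** 2 - 1.0) / p.R_I + 1.0 / (p.b * p.R_w)
    return float(out) if out.ndim == 0 else out


def nullclines(u, p: ModelParams, I: float = 0.0) -> NullclineValues:
    """Recovery current on each nullcline at voltage ``u`` under drive ``I``.

    The ``dw/dt = 0`` branch is the line ``w = u/(b R_w)``; the ``du/dt = 0``
    branch is the cubic ``w = I - (1/R_I)(u^3/(3 u_1^2) - u)``.  Fixed points
    sit at their intersections.
    """
    u_arr = np.asarray(u, dtype=float)
    w_w = u_arr / (p.b * p.R_w)
    w_u = I - (u_arr ** 3 / (3.0 * p.u_1 ** 2) - u_arr) / p.R_I
    if u_arr.ndim == 0:
        return NullclineValues(w_on_u_nullcline=float(w_u), w_on_w_nullcline=float(w_w))
    return NullclineValues(w_on_u_nullcline=w_u, w_on_w_nullcline=w_w)


# -- fixed points --------------------------------------------------------------

_MERGE_TOL = 1e-9  # roots closer than this (times u_1) merge: saddle-node tangency


def _real_cubic_roots(c3: float, c1: float, c0: float) -> list[float]:
    """Real roots of the depressed cubic c3*u^3 + c1*u + c0 = 0 (c3 > 0),
    by the trigonometric / Cardano closed form."""
    pp = c1 / c3
    qq = c0 / c3
    if pp == 0.0 and qq == 0.0:
        return [0.0]
    disc = -4.0 * pp ** 3 - 27.0 * qq ** 2
    if pp < 0 and disc >= 0:
        # three real roots (possibly degenerate): trigonometric form
        m = 2.0 * math.sqrt(-pp / 3.0)
        arg = 3.0 * qq / (pp * m)  # = (3q/2p)*sqrt(-3/p)
        arg = min(1.0, max(-1.0, arg))
        theta = math.acos(arg)
        return [m * math.cos((theta - 2.0 * math.pi * k) / 3.0) for k in range(3)]
    # one real root: Cardano
    half_q = qq / 2.0
    delta = math.sqrt(half_q ** 2 + (pp / 3.0) ** 3)
    return [math.cbrt(-half_q + delta) + math.cbrt(-half_q - delta)]


def fixed_points(I: float, p: ModelParams) -> list[State]:
    """All fixed points of the model under constant drive ``I``.

    Solves ``stationary_current(u) = I`` in closed form (depressed cubic),
    polishes each root with Newton steps on the residual, merges
    saddle-node-degenerate roots, and pairs each voltage with
    ``w* = u*/(b R_w)``.  Returned sorted by ascending ``u``; the residual
    satisfies ``|I(u*) - I| < 1e-10 * max(1, |I|)``.
    """
    c3 = 1.0 / (3.0 * p.u_1 ** 2 * p.R_I)
    c1 = 1.0 / (p.b * p.R_w) - 1.0 / p.R_I
    roots = _real_cubic_roots(c3, c1, -float(I))

    polished = []
    for u in roots:
        for _ in range(4):
            f = stationary_current(u, p) - I
            df = stationary_current_slope(u, p)
            if df == 0.0 or not math.isfinite(f):
                break
            step = f / df
            u -= step
            if abs(step) < 1e-15 * max(1.0, abs(u)):
                break
        polished.append(u)

    polished.sort()
    merged: list[float] = []
    for u in polished:
        if merged and abs(u - merged[-1]) < _MERGE_TOL * p.u_1:
            continue
        merged.append(u)

    return [State(u=u, w=u / (p.b * p.R_w)) for u in merged]
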