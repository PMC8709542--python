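"""Linear stability analysis: Jacobian, eigenvalues, fixed-point
classification and closed bifurcation curves.

Conventions follow the usual dimensionless reporting of the two-variable
model: the trace is given in units of ``1/tau_m`` (``trace_norm =
tr(J) * tau_m``) and the determinant in units of ``1/tau_m^2``
(``det_norm = det(J) * tau_m^2 = epsilon * [b (u^2/u_1^2 - 1) + r]``), so
the analytic bifurcation conditions read off directly:

* ``trace_norm = 0`` with ``det_norm > 0`` -- Hopf bifurcation, at
  ``u_H = u_1 sqrt(1 - epsilon b)``;
* ``det_norm = 0`` -- saddle-node of the three-valued stationary curve,
  at ``u_SN = u_1 sqrt(1 - r/b)`` (present when ``r/b < 1``);
* ``r = b`` -- pitchfork of the ``I = 0`` fixed-point set.

Eigenvalues themselves are reported in absolute units (1/s).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ContractViolationError
from .model import ModelParams, State, stationary_current, stationary_current_slope

__all__ = [
    "FixedPointClass",
    "StabilityReport",
    "BifurcationSummary",
    "jacobian",
    "trace_norm",
    "det_norm",
    "stability_report",
    "bifurcation_summary",
    "stability_scan",
]

#: classification boundary tolerances (far below the 1e-4 print precision
#: of the quantities they gate)
TRACE_TOL = 1e-9
DET_TOL = 1e-12


class FixedPointClass(str, enum.Enum):
    STABLE_NODE = "stable_node"
    STABLE_SPIRAL = "stable_spiral"
    UNSTABLE_NODE = "unstable_node"
    UNSTABLE_SPIRAL = "unstable_spiral"
    SADDLE = "saddle"
    NON_HYPERBOLIC = "non_hyperbolic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def jacobian(u: float, p: ModelParams) -> np.ndarray:
    """Jacobian of the vector field at voltage ``u`` (any bias), units 1/s."""
    return np.array(
        [
            [(1.0 - u ** 2 / p.u_1 ** 2) / p.tau_m, -p.R_I / p.tau_m],
            [1.0 / (p.R_w * p.tau_k), -p.b / p.tau_k],
        ]
    )


def trace_norm(u, p: ModelParams):
    """tr(J) * tau_m = (1 - u^2/u_1^2) - epsilon*b  (dimensionless)."""
    u = np.asarray(u, dtype=float)
    out = (1.0 - u ** 2 / p.u_1 ** 2) - p.epsilon * p.b
    return float(out) if out.ndim == 0 else out


def det_norm(u, p: ModelParams):
    """det(J) * tau_m^2 = epsilon * [b (u^2/u_1^2 - 1) + r]  (dimensionless).

    Its sign equals the sign of the dc resistance of the equivalent circuit
    at the same bias (1/R_dc = dI/du on the stationary curve).
    """
    u = np.asarray(u, dtype=float)
    out = p.epsilon * (p.b * (u ** 2 / p.u_1 ** 2 - 1.0) + p.r)
    return float(out) if out.ndim == 0 else out


def _classify(tr_n: float, det_n: float, disc: float) -> FixedPointClass:
    if abs(det_n) < DET_TOL:
        return FixedPointClass.NON_HYPERBOLIC
    if det_n < 0:
        return FixedPointClass.SADDLE
    if abs(tr_n) < TRACE_TOL:
        return FixedPointClass.NON_HYPERBOLIC
    if tr_n < 0:
        return FixedPointClass.STABLE_SPIRAL if disc < 0 else FixedPointClass.STABLE_NODE
    return FixedPointClass.UNSTABLE_SPIRAL if disc < 0 else FixedPointClass.UNSTABLE_NODE


@dataclass(frozen=True)
class StabilityReport:
    """Normal-mode analysis of one bias voltage.

    ``eigenvalues`` are in absolute 1/s units; ``eigenvalues_norm`` are the
    same pair multiplied by tau_m (the dimensionless reporting convention).
    """

    fixed_point: State
    trace_norm: float
    det_norm: float
    discriminant: float
    eigenvalues: tuple[complex, complex]
    eigenvalues_norm: tuple[complex, complex]
    klass: FixedPointClass


def stability_report(
    u: float, p: ModelParams, I_check: Optional[float] = None
) -> StabilityReport:
    """Classify the linearization at bias voltage ``u``.

    If ``I_check`` is given, ``u`` must actually be a fixed point of that
    drive (``|I(u) - I_check| < 1e-8``); omit it to analyze ``u`` as a
    hypothetical bias.
    """
    if I_check is not None:
        resid = abs(stationary_current(u, p) - I_check)
        if resid >= 1e-8:
            raise ContractViolationError(
                f"u={u} is not a fixed point of I={I_check} "
                f"(|I(u)-I|={resid:.3g} >= 1e-8)"
            )
    tr_n = trace_norm(u, p)
    det_n = det_norm(u, p)
    disc = tr_n ** 2 - 4.0 * det_n
    # eigenvalues of J from the characteristic quadratic, absolute units
    tr = tr_n / p.tau_m
    det = det_n / p.tau_m ** 2
    sq = np.sqrt(complex(tr ** 2 - 4.0 * det))
    lam1 = (tr - sq) / 2.0
    lam2 = (tr + sq) / 2.0
    lams = (complex(lam1), complex(lam2))
    return StabilityReport(
        fixed_point=State(u=float(u), w=float(u) / (p.b * p.R_w)),
        trace_norm=float(tr_n),
        det_norm=float(det_n),
        discriminant=float(disc),
        eigenvalues=lams,
        eigenvalues_norm=(lams[0] * p.tau_m, lams[1] * p.tau_m),
        klass=_classify(tr_n, det_n, disc),
    )


@dataclass(frozen=True)
class BifurcationSummary:
    """Closed bifurcation structure of a parameter set.

    Voltages are the positive branch; the model is odd in ``u`` so each
    bifurcation occurs at ``+-`` the reported value.
    """

    hopf_voltage: Optional[float]
    hopf_current: Optional[float]
    saddle_node_voltage: Optional[float]
    pitchfork: bool


def bifurcation_summary(p: ModelParams) -> BifurcationSummary:
    """Locate Hopf, saddle-node and pitchfork bifurcations.

    The Hopf voltage is found by a bracketed root solve of
    ``trace_norm(u) = 0`` on ``(0, u_1)`` (present iff ``1 - epsilon*b > 0``);
    the saddle-node voltage by a root solve of ``dI/du = 0`` on the same
    interval (present iff ``r/b < 1``); the pitchfork flag marks ``r = b``.
    """
    u_H = I_H = None
    if 1.0 - p.epsilon * p.b > 0:
        u_H = brentq(lambda u: trace_norm(u, p), 0.0, p.u_1, xtol=1e-15, rtol=1e-15)
        I_H = stationary_current(u_H, p)
    u_SN = None
    if p.r / p.b < 1.0:
        u_SN = brentq(
            lambda u: stationary_current_slope(u, p), 0.0, p.u_1, xtol=1e-15, rtol=1e-15
        )
    return BifurcationSummary(
        hopf_voltage=u_H,
        hopf_current=I_H,
        saddle_node_voltage=u_SN,
        pitchfork=bool(abs(p.r - p.b) < 1e-12),
    )


def stability_scan(p: ModelParams, u_grid: Sequence[float]) -> pd.DataFrame:
    """Row-wise stability report over an ascending voltage grid.

    Returns a DataFrame with columns ``u, trace, det, disc, class``; sign
    changes of ``trace`` bracket the Hopf voltages and sign changes of
    ``det`` bracket the saddle-node voltages.
    """
    u_grid = np.asarray(u_grid, dtype=float)
    if u_grid.ndim != 1 or not np.all(np.isfinite(u_grid)):
        raise ValueError("u_grid must be a 1-D finite sequence")
    if np.any(np.diff(u_grid) <= 0):
        raise ValueError("u_grid must be strictly ascending")
    rows = []
    for u in u_grid:
        rep = stability_report(u, p)
        rows.append((u, rep.trace_norm, rep.det_norm, rep.discriminant, rep.klass.value))
    return pd.DataFrame(rows, columns=["u", "trace", "det", "disc", "class"])
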