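"""Small-signal impedance of the FitzHugh-Nagumo membrane and its
equivalent circuit.

Linearizing the model at a bias voltage ``u`` and Laplace-transforming
(``d/dt -> s``, ``s = i omega``) gives the admittance of three parallel
branches -- membrane capacitor, bias-dependent channel resistor, and the
recovery branch (resistor in series with a chemical inductor)::

    Y(s) = s C_m + G_b + 1 / (R_a + s L),        Z(s) = 1 / Y(s)

with ``C_m = tau_m/R_I``, ``G_b = (u^2/u_1^2 - 1)/R_I`` (negative inside
the NDR window ``|u| < u_1``), ``R_a = b R_w`` and ``L = tau_k R_w``.
``Z(0) = R_dc = 1/(G_b + 1/R_a)`` equals the reciprocal slope of the
stationary current-voltage curve, and ``|Z| -> 1/(omega C_m)`` at high
frequency (no series resistance, so every spectrum ends at the origin).

The zeros of ``Y(s)`` -- the roots of
``s^2 C_m L + s (C_m R_a + L G_b) + (R_a G_b + 1) = 0`` -- are exactly the
eigenvalues of the Jacobian at the same bias.  Under constant-current
drive they are the poles of ``Z``, so a Hopf bifurcation is signalled on
the spectrum by a purely imaginary pole pair at ``omega = sqrt(det J)``
(Nyquist criterion for a galvanostatically operated cell).

Spectra are classified into five regimes:

* ``NEGATIVE_RDC`` -- the dc intercept is on the negative real axis
  (three-valued stationary curve, central saddle).
* ``HIDDEN_NDR`` -- positive ``R_dc`` but the spectrum crosses into
  Re Z < 0 through the *upper* half-plane (fourth quadrant of the
  conventional -Im Z plot): the bias sits on the unstable-focus side of
  the Hopf and the neuron spikes.
* ``INDUCTIVE_LOOP`` -- stable bias whose spectrum crosses the real axis
  at finite frequency and loops below it.
* ``BENT_ARC`` -- no crossing, but the inductive branch cancels a large
  fraction of the low-frequency capacitive susceptance, flattening the
  arc against the real axis.
* ``RC_ARC`` -- a plain capacitive arc.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, stationary_current

__all__ = [
    "ECElements",
    "ImpedanceSpectrum",
    "SpectrumClass",
    "ec_elements",
    "impedance_at",
    "admittance_at",
    "spectrum",
    "classify_spectrum",
    "classify_spectrum_detail",
    "impedance_zeros",
    "default_omega_window",
]

#: fraction of the low-frequency capacitive susceptance that the inductive
#: branch must cancel for a non-crossing spectrum to count as "bent"
BEND_THRESHOLD = 0.5


class SpectrumClass(str, enum.Enum):
    RC_ARC = "RC_ARC"
    BENT_ARC = "BENT_ARC"
    INDUCTIVE_LOOP = "INDUCTIVE_LOOP"
    HIDDEN_NDR = "HIDDEN_NDR"
    NEGATIVE_RDC = "NEGATIVE_RDC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ECElements:
    """Equivalent-circuit element values at one bias voltage.

    ``G_b`` is stored as a conductance (1/R_b) so the element stays regular
    at ``|u| = u_1`` where the channel branch is open.  ``R_dc`` is signed
    and infinite at a saddle-node bias (the stationary curve turns there).
    """

    C_m: float
    G_b: float
    R_a: float
    L: float
    R_dc: float

    @property
    def R_b(self) -> float:
        """Signed channel branch resistance 1/G_b (ohm; +-inf at |u| = u_1)."""
        if self.G_b == 0.0:
            return math.inf
        return 1.0 / self.G_b


def ec_elements(u: float, p: ModelParams) -> ECElements:
    """Equivalent-circuit elements at bias voltage ``u``."""
    C_m = p.tau_m / p.R_I
    G_b = (u ** 2 / p.u_1 ** 2 - 1.0) / p.R_I
    R_a = p.b * p.R_w
    L = p.tau_k * p.R_w
    g_dc = G_b + 1.0 / R_a
    R_dc = math.inf if g_dc == 0.0 else 1.0 / g_dc
    return ECElements(C_m=C_m, G_b=G_b, R_a=R_a, L=L, R_dc=R_dc)


def admittance_at(u: float, p: ModelParams, omega):
    """Small-signal admittance Y(i omega) (S); vectorized in ``omega``."""
    ec = ec_elements(u, p)
    w = np.asarray(omega, dtype=float)
    s = 1j * w
    out = s * ec.C_m + ec.G_b + 1.0 / (ec.R_a + s * ec.L)
    return complex(out) if out.ndim == 0 else out


def impedance_at(u: float, p: ModelParams, omega):
    """Small-signal impedance Z(i omega) (ohm); vectorized in ``omega``.

    ``Z(0)`` is the signed dc resistance; the parallel-branch form is
    pole-free for real ``omega`` except exactly at a Hopf bias, where a
    purely imaginary pole pair sits at ``omega = sqrt(det J)``.
    """
    y = admittance_at(u, p, omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        if np.isscalar(y) or np.ndim(y) == 0:
            return complex(np.inf) if y == 0 else 1.0 / y
        return np.where(y == 0, np.inf + 0j, 1.0 / y)


def default_omega_window(p: ModelParams) -> tuple[float, float]:
    """Default angular-frequency window [1e-3/tau_k, 1e3/tau_m] rad/s:
    spans both relaxation times with three decades of margin, so the dc
    and capacitive asymptotes used by the classifier are reached."""
    return 1e-3 / p.tau_k, 1e3 / p.tau_m


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Impedance spectrum at one bias: ``omegas`` ascending with an explicit
    ``omega = 0`` head entry whose Z equals the signed dc resistance."""

    bias_u: float
    bias_I: float
    omegas: np.ndarray
    Z: np.ndarray
    regime: SpectrumClass


def spectrum(
    u: float,
    p: ModelParams,
    omega_min: Optional[float] = None,
    omega_max: Optional[float] = None,
    points_per_decade: int = 60,
) -> ImpedanceSpectrum:
    """Log-spaced impedance spectrum at bias ``u`` with attached regime label.

    The grid spans ``[omega_min, omega_max]`` (defaults to
    :func:`default_omega_window`) at ``points_per_decade``, with an
    ``omega = 0`` entry prepended.
    """
    if omega_min is None or omega_max is None:
        lo, hi = default_omega_window(p)
        omega_min = lo if omega_min is None else omega_min
        omega_max = hi if omega_max is None else omega_max
    if not (0 < omega_min < omega_max):
        raise ValueError(f"need 0 < omega_min < omega_max, got ({omega_min}, {omega_max})")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    decades = math.log10(omega_max / omega_min)
    n = max(2, int(round(decades * points_per_decade)) + 1)
    omegas = np.logspace(math.log10(omega_min), math.log10(omega_max), n)
    omegas = np.concatenate([[0.0], omegas])
    Z = impedance_at(u, p, omegas)
    return ImpedanceSpectrum(
        bias_u=float(u),
        bias_I=float(stationary_current(u, p)),
        omegas=omegas,
        Z=np.asarray(Z, dtype=complex),
        regime=classify_spectrum(u, p),
    )


class SpectrumDiagnostics(NamedTuple):
    """Regime label plus the decisive frequencies behind it."""

    regime: SpectrumClass
    re_crossing_omega: Optional[float]  # where Re Z changes sign, rad/s
    im_crossing_omega: Optional[float]  # where the arc crosses the real axis, rad/s
    bend_ratio: float  # kappa = L/(R_a^2 C_m); > 1 <=> real-axis crossing


def _refine_sign_change(f, w: np.ndarray, values: np.ndarray) -> Optional[float]:
    """First sign change of ``values`` over grid ``w``, refined by brentq."""
    sign = np.sign(values)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    return float(brentq(f, w[i], w[i + 1], xtol=1e-300, rtol=1e-14))


def classify_spectrum_detail(u: float, p: ModelParams) -> SpectrumDiagnostics:
    """Classify the spectrum at bias ``u`` and report the decisive crossings.

    Decision cascade (each crossing located by sign change on a
    60-points-per-decade scan of the default window plus bisection):

    1. dc conductance negative -> NEGATIVE_RDC;
    2. Re Z changes sign at finite omega *and* Im Z > 0 there (the Nyquist
       curve enters the left half-plane through the fourth quadrant of the
       -Im Z plot; equivalent to tr J > 0, the unstable-focus side of the
       Hopf) -> HIDDEN_NDR;
    3. Im Z > 0 somewhere (real-axis crossing at finite frequency;
       equivalent to kappa = L/(R_a^2 C_m) > 1, the loop condition
       tau_k > R_a C_m at b = 1) -> INDUCTIVE_LOOP;
    4. no crossing but kappa >= 0.5 (the arc is pressed against the real
       axis by the inductive branch; tangency kappa = 1 included)
       -> BENT_ARC;
    5. otherwise RC_ARC.
    """
    ec = ec_elements(u, p)
    kappa = ec.L / (ec.R_a ** 2 * ec.C_m)
    g_dc = ec.G_b + 1.0 / ec.R_a

    if g_dc < 0:
        return SpectrumDiagnostics(SpectrumClass.NEGATIVE_RDC, None, None, kappa)

    lo, hi = default_omega_window(p)
    # extend the window until the high-frequency Re-asymptote (sign of G_b)
    # is reached, so a Re crossing cannot be missed for biases near u_1
    while ec.G_b < 0 and admittance_at(u, p, hi).real > 0:
        hi *= 1e3
    n = max(2, int(round(math.log10(hi / lo) * 60)) + 1)
    w = np.logspace(math.log10(lo), math.log10(hi), n)
    Z = impedance_at(u, p, w)

    w_re = _refine_sign_change(lambda x: impedance_at(u, p, x).real, w, Z.real)
    w_im = _refine_sign_change(lambda x: impedance_at(u, p, x).imag, w, Z.imag)
    if w_im is None and np.any(Z.imag > 0):
        # crossing below the grid floor: the whole low end is already inductive
        w_im = float(w[np.nonzero(Z.imag > 0)[0][-1]])

    if w_re is not None and impedance_at(u, p, w_re * (1 - 1e-9)).imag > 0:
        return SpectrumDiagnostics(SpectrumClass.HIDDEN_NDR, w_re, w_im, kappa)
    if w_im is not None:
        return SpectrumDiagnostics(SpectrumClass.INDUCTIVE_LOOP, w_re, w_im, kappa)
    if kappa >= BEND_THRESHOLD:
        return SpectrumDiagnostics(SpectrumClass.BENT_ARC, w_re, None, kappa)
    return SpectrumDiagnostics(SpectrumClass.RC_ARC, w_re, None, kappa)


def classify_spectrum(u: float, p: ModelParams) -> SpectrumClass:
    """Regime label of the spectrum at bias ``u`` (see
    :func:`classify_spectrum_detail` for the decisive frequencies)."""
    return classify_spectrum_detail(u, p).regime


def impedance_zeros(u: float, p: ModelParams) -> tuple[complex, complex]:
    """Natural frequencies of the small-signal response at bias ``u``:
    the two roots of ``s^2 C_m L + s (C_m R_a + L G_b) + (R_a G_b + 1) = 0``
    (zeros of the admittance; poles of Z under constant-current drive).

    They equal the Jacobian eigenvalues at the same bias, which is the
    content of the Nyquist stability criterion here: a root pair on the
    imaginary axis marks the Hopf bifurcation, a real pair of opposite
    signs the saddle region.
    """
    ec = ec_elements(u, p)
    roots = np.roots([ec.C_m * ec.L, ec.C_m * ec.R_a + ec.L * ec.G_b, ec.R_a * ec.G_b + 1.0])
    roots = sorted((complex(z) for z in roots), key=lambda z: (z.real, z.imag))
    return roots[0], roots[1]
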