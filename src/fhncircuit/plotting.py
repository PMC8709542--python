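"""Optional plot helpers (matplotlib imported lazily; install the
``plot`` extra).  The complex-plane plot follows the electrochemistry
convention of -Im Z on the vertical axis, so the inductive loop appears
in the fourth quadrant; the stored spectrum itself is untransformed."""

from __future__ import annotations

from .dynamics import PhasePortrait
from .impedance import ImpedanceSpectrum


def _require_pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install fhncircuit[plot])") from exc
    return plt


def plot_nyquist(spec: ImpedanceSpectrum, ax=None):
    """Complex-plane (Nyquist) plot: Re Z vs -Im Z, dc point marked."""
    plt = _require_pyplot()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spec.Z[1:].real, -spec.Z[1:].imag, "-")
    ax.plot(spec.Z[0].real, -spec.Z[0].imag, "o", label=r"$\omega = 0$")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.axvline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel(r"$Z'$ / $\Omega$")
    ax.set_ylabel(r"$-Z''$ / $\Omega$")
    ax.set_title(f"u = {spec.bias_u:g} V: {spec.regime}")
    ax.legend()
    return ax


def plot_phase_portrait(portrait: PhasePortrait, ax=None):
    """Trajectories over the nullclines, fixed points marked by class
    (filled = stable, open = unstable/saddle)."""
    plt = _require_pyplot()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(portrait.u_grid, portrait.w_on_u_nullcline, label=r"$\dot u = 0$")
    ax.plot(portrait.u_grid, portrait.w_on_w_nullcline, label=r"$\dot w = 0$")
    for traj in portrait.trajectories:
        ax.plot(traj.u, traj.w, lw=1)
        ax.plot(traj.u[0], traj.w[0], ".", color="k", ms=4)
    for rep in portrait.fixed_point_reports:
        stable = rep.klass.value.startswith("stable")
        ax.plot(
            rep.fixed_point.u,
            rep.fixed_point.w,
            "o",
            mfc="k" if stable else "none",
            mec="k",
        )
    ax.set_xlabel("u / V")
    ax.set_ylabel("w / A")
    ax.legend()
    return ax
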