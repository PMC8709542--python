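"""Built-in parameter presets.

Models A-F share R_I = 0.5 ohm, tau_m = 1e-2 s and u_1 = 1 V and differ
in (b, r, epsilon); they span the spectral taxonomy from a plain RC arc
(A) through inductive loops and hidden negative impedance (C, D) to the
bistable / limit-cycle negative-R_dc regimes (E, F).  ``fig1a`` and
``fig1c`` are the two stationary-curve illustration sets (b = 0.8,
epsilon = 0.1, with r = 0.4 and r = 1 respectively); ``fig1c`` carries
the Hopf anchor u_H = +-0.9591 V, I_H = +-1.0678 A.

Model C's epsilon is stored as the rounded 0.316 (its tabulated Hopf
voltage 0.82690 is consistent with the unrounded 10^(-1/2) = 0.316228;
the rounded value gives 0.82704).
"""

from __future__ import annotations

from .exceptions import ConfigError
from .model import ModelParams

__all__ = ["PRESETS", "PRESET_NAMES", "preset"]

# name -> (b, r, epsilon)
_TABLE: dict[str, tuple[float, float, float]] = {
    "A": (1.0, 1.2, 20.0),
    "B": (1.0, 1.2, 1.8),
    "C": (1.0, 1.2, 0.316),
    "D": (1.0, 1.2, 0.01),
    "E": (1.2, 0.8, 0.01),
    "F": (1.1, 0.8, 0.01),
    "fig1a": (0.8, 0.4, 0.1),
    "fig1c": (0.8, 1.0, 0.1),
}

PRESETS: dict[str, ModelParams] = {
    name: ModelParams.from_ratios(b=b, r=r, epsilon=eps, tau_m=1e-2, R_I=0.5, u_1=1.0)
    for name, (b, r, eps) in _TABLE.items()
}

PRESET_NAMES: tuple[str, ...] = tuple(PRESETS)


def preset(name: str) -> ModelParams:
    """Return a built-in parameter set by name (A-F, fig1a, fig1c)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
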