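"""One-call reproduction of the tabulated quantitative anchors: the
Hopf-voltage column of the model table and the Hopf point of the
``fig1c`` stationary curve."""

from __future__ import annotations

import pandas as pd

from .presets import preset
from .stability import bifurcation_summary

__all__ = ["repro_table1", "repro_fig1c"]


def repro_table1() -> pd.DataFrame:
    """Hopf voltage per preset model A-F, blank where none exists
    (epsilon*b >= 1), printed to 5 decimals in the ``u_Hopf`` column."""
    rows = []
    for name in "ABCDEF":
        p = preset(name)
        summ = bifurcation_summary(p)
        rows.append(
            {
                "model": name,
                "b": p.b,
                "r": p.r,
                "epsilon": p.epsilon,
                "u_Hopf": "" if summ.hopf_voltage is None else f"{summ.hopf_voltage:.5f}",
            }
        )
    return pd.DataFrame(rows)


def repro_fig1c() -> dict:
    """Hopf voltage and current of the ``fig1c`` parameter set, both signs
    (the model is odd in u, so the negative branch is the exact negation)."""
    summ = bifurcation_summary(preset("fig1c"))
    return {
        "u_H": summ.hopf_voltage,
        "I_H": summ.hopf_current,
        "u_H_negative": -summ.hopf_voltage,
        "I_H_negative": -summ.hopf_current,
    }
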