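"""CaMKII activation dynamics and the beta-adrenergic (PKA) cascade.

CaMKII follows the classic calmodulin-trapping description: a
calcium-bound fraction activates rapidly with dyadic calcium, and a trapped
(autonomous) fraction builds up with sustained activity, so faster pacing
raises steady-state activity.

The beta-adrenergic arm is a reduced cascade: an agonist drive (0..1, with
1 = saturating isoprenaline-like stimulation) sets PKA activity through a
first-order step, and PKA activity sets per-substrate phosphorylation
fractions (ICaL, IKs, phospholamban/SERCA, RyR, NaK pump, troponin-I /
crossbridges), each first-order with its own time constant. Substrate
phosphorylation translates into multiplicative modifiers on the targets;
with zero agonist and resting calcium every modifier relaxes to 1.
"""

from __future__ import annotations

import numpy as np

from ._kernel import OX, rhs_py
from .parameters import Parameters
from .states import IX

__all__ = ["camkii_dynamics", "bars_dynamics", "camkii_targets",
           "pka_targets", "agonist_from_concentration", "set_bars"]

PKA_SUBSTRATES = ["p_ical", "p_iks", "p_plb", "p_ryr", "p_inak", "p_tni"]


def camkii_dynamics(state: np.ndarray, p: Parameters) -> dict:
    """Active CaMKII fraction, its trap-state derivative, and the current
    modifier set."""
    dy, out = rhs_py(0.0, state, p.vec)
    camka = float(out[OX["camk_active"]])
    frac = camka / (camka + p["kmcamk"])
    return {"active": camka, "active_fraction": frac,
            "d_trap": float(dy[IX["camk_trap"]]),
            "targets": camkii_targets(p, frac)}


def camkii_targets(p: Parameters, frac: float) -> dict:
    """Multiplicative modifiers applied by CaMKII at active fraction ``frac``
    (all 1 at zero activity)."""
    return {
        "ICaL": 1.0 + p["c_camk_ical"] * frac,
        "Jup_affinity": 1.0 + p["c_camk_jup"] * frac,   # divides SERCA Kmf
        "RyR": 1.0 + p["c_camk_ryr"] * frac,
        "INaL_phospho_fraction": frac,                   # gates hL <-> hLp mix
    }


def bars_dynamics(state: np.ndarray, p: Parameters,
                  agonist: float | bool | None = None) -> dict:
    """PKA cascade derivatives and the PKA target-modifier set.

    ``agonist`` overrides the parameter-set drive (True = saturating)."""
    p2 = p
    if agonist is not None:
        p2 = p.copy()
        p2.set("agonist", 1.0 if agonist is True else float(agonist))
    dy, _ = rhs_py(0.0, state, p2.vec)
    phos = {k: float(state[IX[k]]) for k in PKA_SUBSTRATES}
    return {"d_pka": float(dy[IX["a_pka"]]),
            "d_phospho": {k: float(dy[IX[k]]) for k in PKA_SUBSTRATES},
            "phospho": phos,
            "targets": pka_targets(p, phos)}


def pka_targets(p: Parameters, phos: dict) -> dict:
    """Multiplicative modifiers at the given phosphorylation fractions."""
    return {
        "ICaL": 1.0 + p["c_pka_ical"] * phos["p_ical"],
        "ICaL_act_shift_mV": -p["c_pka_dshift"] * phos["p_ical"],
        "IKs": 1.0 + p["c_pka_iks"] * phos["p_iks"],
        "Jup_affinity": 1.0 + p["c_pka_plb"] * phos["p_plb"],
        "Jup_vmax": 1.0 + p["c_pka_vup"] * phos["p_plb"],
        "RyR": 1.0 + p["c_pka_ryr"] * phos["p_ryr"],
        "INaK": 1.0 + p["c_pka_inak"] * phos["p_inak"],
        "Ca50": 1.0 + p["c_pka_ca50"] * phos["p_tni"],
        "TRPN_rate": 1.0 + p["c_pka_ktrpn"] * phos["p_tni"],
        "XB_rate": 1.0 + p["c_pka_xb"] * phos["p_tni"],
    }


def agonist_from_concentration(iso_um: float, ec50_um: float = 0.06) -> float:
    """Graded agonist drive from an isoprenaline-like concentration (uM)."""
    return iso_um / (iso_um + ec50_um)


def set_bars(p: Parameters, on: bool | float) -> Parameters:
    """Return a copy of ``p`` with the beta-adrenergic switch set
    (False/0 = off, True/1 = saturating, or a graded value)."""
    p2 = p.copy()
    p2.set("agonist", 1.0 if on is True else float(on))
    return p2
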