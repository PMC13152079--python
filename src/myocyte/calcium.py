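"""Calcium-handling fluxes: SR release (hybrid ICaL-coupled + Ca-sensitive
refractory RyR), SERCA uptake, leak, buffering and inter-compartment
diffusion."""

from __future__ import annotations

import numpy as np

from ._kernel import OX, rhs_py
from .biomarkers import clearance_fractions  # re-export  # noqa: F401
from .parameters import Parameters
from .states import IX

__all__ = ["compute_Jrel", "compute_Jup_Jleak",
           "compute_buffering_and_diffusion", "ryr_transition_rates",
           "clearance_fractions", "buffer_equilibrium"]


def compute_Jrel(state: np.ndarray, p: Parameters) -> dict:
    """SR release flux (mM/ms, bulk-myoplasm basis) split into the
    ICaL-coupled and calcium-sensitive components, plus RyR state
    derivatives."""
    dy, out = rhs_py(0.0, state, p.vec)
    return {
        "Jrel": float(out[OX["jrel"]]),
        "Jrel_ca": float(out[OX["jrel_ca"]]),
        "Jrel_icl": float(out[OX["jrel_icl"]]),
        "dRyR": {k: float(dy[IX[k]]) for k in ("ryr_r", "ryr_o", "ryr_i")},
    }


def compute_Jup_Jleak(state: np.ndarray, p: Parameters) -> dict:
    dy, out = rhs_py(0.0, state, p.vec)
    return {"Jup": float(out[OX["jup"]]), "Jleak": float(out[OX["jleak"]])}


def compute_buffering_and_diffusion(state: np.ndarray, p: Parameters) -> dict:
    """Buffer occupancy derivatives (mM/ms) and diffusion fluxes between
    compartments (mM/ms, on the donor compartment's volume basis)."""
    dy, out = rhs_py(0.0, state, p.vec)
    buffers = {k: float(dy[IX[k]]) for k in
               ("b_cam", "b_sll_sl", "b_slh_sl", "b_sll_d", "b_slh_d",
                "b_csqn", "ca_trpn")}
    jd_ds = (state[IX["ca_dyad"]] - state[IX["ca_sl"]]) / p["tau_ds"]
    jd_sm = (state[IX["ca_sl"]] - state[IX["ca_myo"]]) / p["tau_sm"]
    jd_na = (state[IX["na_sl"]] - state[IX["na_myo"]]) / p["tau_na"]
    return {"buffer_derivatives": buffers,
            "Jdiff_dyad_sl": float(jd_ds), "Jdiff_sl_myo": float(jd_sm),
            "Jdiff_na": float(jd_na)}


def ryr_transition_rates(ca_dyad: float, ca_sr: float, p: Parameters,
                         pka: float = 0.0, camk: float = 0.0) -> dict:
    """Instantaneous RyR transition rates (per ms) at clamped calcium.

    The SR-load dependence enters through ``kcasr``: a depleted SR slows
    opening and speeds calcium-dependent inactivation; an overloaded SR does
    the opposite, which is what lets store overload trigger spontaneous
    release."""
    kcasr = p["maxsr"] - (p["maxsr"] - p["minsr"]) / \
        (1.0 + (p["ec50sr"] / ca_sr) ** p["hsr"])
    sens = (1.0 + p["c_pka_ryr"] * pka) * (1.0 + p["c_camk_ryr"] * camk)
    ko_eff = p["ko_ryr"] * sens / kcasr
    ki_eff = p["ki_ryr"] * kcasr
    cad2 = ca_dyad ** 2
    so = (ca_sr - p["casr_so_thr"]) * p["so_scale"]
    if so > 0.0:
        cad2 += so * so                     # store-overload self-triggering
    kim_eff = p["kim"] / (1.0 + (ca_dyad / p["km_refrac"]) ** 2)
    return {
        "k_open": ko_eff * cad2,             # R -> O (also RI -> I)
        "k_close": p["kom"],                 # O -> R (also I -> RI)
        "k_inact": ki_eff * ca_dyad,         # O -> I (also R -> RI)
        "k_recover": kim_eff,                # I -> O (also RI -> R)
        "kcasr": kcasr,
    }


def buffer_equilibrium(ca: float, bmax: float, kon: float, koff: float) -> float:
    """Closed-form bound concentration of a 1:1 buffer at clamped free Ca."""
    kd = koff / kon
    return bmax * ca / (kd + ca)
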