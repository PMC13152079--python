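"""Sarcolemmal current computations on a given state.

These are thin, readable views over the compiled RHS: each helper evaluates
the full kernel once at the supplied state and returns the named subset, so
values are guaranteed identical to what the integrator uses.
"""

from __future__ import annotations

import numpy as np

from ._kernel import OX, rhs_py
from .parameters import Parameters
from .states import IX, validate_state

__all__ = ["reversal_potentials", "compute_currents", "compute_ICaL",
           "compute_INaK", "compute_INaCa", "compute_remaining_currents",
           "gate_derivatives"]

_CURRENT_KEYS = ["ina", "inal", "ito", "ical", "ical_d", "ical_sl", "icana",
                 "icak", "ikr", "iks", "ik1", "inaca", "inaca_d", "inaca_sl",
                 "inak", "ipca", "inab", "icab", "ikb", "iclca", "iclb"]


def _eval(state: np.ndarray, p: Parameters, t: float = 0.0):
    validate_state(state)
    return rhs_py(t, state, p.vec)


def reversal_potentials(state: np.ndarray, p: Parameters) -> dict:
    """Nernst potentials (mV) for Na, K (and the IKs mixed reversal) and Cl."""
    _, out = _eval(state, p)
    return {k: float(out[OX[f"e_{k.lower()}"]]) for k in ("Na", "K", "Ks", "Cl")}


def compute_currents(state: np.ndarray, p: Parameters) -> dict:
    """Every sarcolemmal current (uA/uF) at the supplied state."""
    _, out = _eval(state, p)
    return {k: float(out[OX[k]]) for k in _CURRENT_KEYS}


def compute_ICaL(state: np.ndarray, p: Parameters) -> dict:
    """L-type calcium current components and the dyadic Ca influx they carry.

    Returns the dyad- and subsarcolemmal-face currents, the Na/K sub-fluxes,
    and ``jca_dyad``: the Ca flux into the dyad (mM/ms, dyad volume basis).
    """
    from .parameters import ACAP, FARADAY, V_DYAD
    _, out = _eval(state, p)
    ical_d = float(out[OX["ical_d"]])
    return {
        "ICaL": float(out[OX["ical"]]),
        "ICaL_dyad": ical_d,
        "ICaL_sl": float(out[OX["ical_sl"]]),
        "ICaNa": float(out[OX["icana"]]),
        "ICaK": float(out[OX["icak"]]),
        "jca_dyad": -ical_d * ACAP / (2.0 * FARADAY * V_DYAD),
    }


def compute_INaK(state: np.ndarray, p: Parameters) -> float:
    _, out = _eval(state, p)
    return float(out[OX["inak"]])


def compute_INaCa(state: np.ndarray, p: Parameters) -> dict:
    """Sodium-calcium exchanger current, total and per membrane face."""
    _, out = _eval(state, p)
    return {"INaCa": float(out[OX["inaca"]]),
            "INaCa_dyad": float(out[OX["inaca_d"]]),
            "INaCa_sl": float(out[OX["inaca_sl"]])}


def compute_remaining_currents(state: np.ndarray, p: Parameters) -> dict:
    cs = compute_currents(state, p)
    for k in ("ical", "ical_d", "ical_sl", "icana", "icak", "inak",
              "inaca", "inaca_d", "inaca_sl"):
        cs.pop(k)
    return cs


def gate_derivatives(state: np.ndarray, p: Parameters) -> dict:
    """d(gate)/dt for every gating variable -- used by equilibrium oracles."""
    dy, _ = _eval(state, p)
    from .states import GATE_NAMES
    return {g: float(dy[IX[g]]) for g in GATE_NAMES}
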