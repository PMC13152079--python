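"""State-vector manifest.

The ordering below is frozen: traces, snapshots and CSV headers all use it,
so results remain comparable across versions.
"""

from __future__ import annotations

import json

import numpy as np

STATE_NAMES: list[str] = [
    "v",                                   # membrane potential (mV)
    "m", "hf", "hs", "j",                  # INa gates
    "ml", "hl", "hlp",                     # INaL gates (hlp: CaMKII-phosphorylated)
    "a", "if_", "is_",                     # Ito gates
    "d", "ff", "fs", "fca", "jca",         # ICaL gates (fca: Ca-dependent inactivation)
    "xrf", "xrs",                          # IKr gates
    "xs1", "xs2",                          # IKs gates
    "ryr_r", "ryr_o", "ryr_i",             # RyR occupancies (refractory = 1-r-o-i)
    "y_icl", "y2_icl",                     # ICaL-coupled RyR subset activation/recovery
    "na_myo", "na_sl",                     # sodium (mM)
    "k_i",                                 # potassium (mM)
    "ca_myo", "ca_sl", "ca_dyad", "ca_sr", # free calcium (mM)
    "b_cam",                               # Ca bound to cytosolic calmodulin-like buffer (mM)
    "b_sll_sl", "b_slh_sl",                # sarcolemmal low/high-affinity buffers, SL (mM)
    "b_sll_d", "b_slh_d",                  # sarcolemmal buffers, dyad (mM)
    "b_csqn",                              # calsequestrin-bound Ca, SR-local (mM)
    "camk_trap",                           # trapped (autonomous) CaMKII fraction
    "a_pka",                               # PKA activity (0..1)
    "p_ical", "p_iks", "p_plb", "p_ryr", "p_inak", "p_tni",  # phosphorylation fractions
    "ca_trpn",                             # troponin-C Ca occupancy (contraction)
    "tm_b", "xb_w", "xb_s",                # tropomyosin blocked, weak/strong crossbridges
]

N_STATES = len(STATE_NAMES)
IX = {n: i for i, n in enumerate(STATE_NAMES)}

# indices of gating variables constrained to [0, 1]
GATE_NAMES = ["m", "hf", "hs", "j", "ml", "hl", "hlp", "a", "if_", "is_",
              "d", "ff", "fs", "fca", "jca", "xrf", "xrs", "xs1", "xs2"]
CONC_NAMES = ["na_myo", "na_sl", "k_i", "ca_myo", "ca_sl", "ca_dyad", "ca_sr"]


def initial_state() -> np.ndarray:
    """A physiologically sensible quiescent starting point (not paced steady
    state; use the shipped snapshots or :func:`myocyte.run_to_steady_state`
    for converged states)."""
    y = np.zeros(N_STATES)
    y[IX["v"]] = -88.0
    # closed/available gate defaults
    for g in ("hf", "hs", "j", "hl", "hlp", "if_", "is_", "ff", "fs",
              "fca", "jca"):
        y[IX[g]] = 1.0
    y[IX["ryr_r"]] = 1.0
    y[IX["y2_icl"]] = 1.0
    y[IX["na_myo"]] = 8.0
    y[IX["na_sl"]] = 8.0
    y[IX["k_i"]] = 144.0
    y[IX["ca_myo"]] = 1.0e-4
    y[IX["ca_sl"]] = 1.0e-4
    y[IX["ca_dyad"]] = 1.0e-4
    y[IX["ca_sr"]] = 1.2
    y[IX["b_cam"]] = 0.01
    y[IX["b_sll_sl"]] = 0.01
    y[IX["b_slh_sl"]] = 0.1
    y[IX["b_sll_d"]] = 0.03
    y[IX["b_slh_d"]] = 0.4
    y[IX["b_csqn"]] = 1.6
    y[IX["ca_trpn"]] = 0.02
    return y


def validate_state(y: np.ndarray) -> None:
    """Reject states violating the manifest invariants, naming the offender."""
    if y.shape != (N_STATES,):
        raise ValueError(f"state vector must have length {N_STATES}")
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise ValueError(f"non-finite state variable: {bad}")
    for n in CONC_NAMES:
        if y[IX[n]] <= 0:
            raise ValueError(f"concentration {n} must be > 0")
    for n in GATE_NAMES:
        if not -1e-9 <= y[IX[n]] <= 1 + 1e-9:
            raise ValueError(f"gate {n} outside [0, 1]")
    s = y[IX["ryr_r"]] + y[IX["ryr_o"]] + y[IX["ryr_i"]]
    if s < -1e-9 or s > 1 + 1e-6:
        raise ValueError("RyR occupancies must lie in [0, 1] and sum to <= 1")


def save_state(y: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        json.dump({n: float(y[i]) for i, n in enumerate(STATE_NAMES)}, fh, indent=1)


def load_state(path) -> np.ndarray:
    with open(path) as fh:
        d = json.load(fh)
    y = np.zeros(N_STATES)
    for n, v in d.items():
        y[IX[n]] = v
    return y
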