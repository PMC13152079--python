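"""Active tension: a Land-type crossbridge model driven by cytosolic calcium.

Troponin-C calcium binding (cooperative, shared with the calcium buffering
bookkeeping) gates tropomyosin unblocking; crossbridges cycle through weak
and strong states; isometric tension is proportional to the strong-state
occupancy with length-dependent activation (the cellular Frank-Starling
effect enters through both the tension scale h(lambda) and the calcium
sensitivity Ca50(lambda)). PKA phosphorylation of troponin-I reduces
calcium sensitivity and accelerates both troponin and crossbridge rates.

Isometric mode at fixed sarcomere stretch (default lambda = 1.1) is the
default everywhere; `set_sarcomere_stretch` exists for length studies.
"""

from __future__ import annotations

import numpy as np

from ._kernel import OX, rhs_py
from .biomarkers import tension_biomarkers  # re-export  # noqa: F401
from .parameters import Parameters
from .states import IX

__all__ = ["contraction_dynamics", "isometric_tension",
           "tension_biomarkers", "set_sarcomere_stretch"]

_CONTR_STATES = ("ca_trpn", "tm_b", "xb_w", "xb_s")


def contraction_dynamics(state: np.ndarray, p: Parameters) -> dict:
    """Derivatives of the contraction states plus the instantaneous active
    tension (kPa)."""
    dy, out = rhs_py(0.0, state, p.vec)
    return {"derivatives": {k: float(dy[IX[k]]) for k in _CONTR_STATES},
            "tension": float(out[OX["tension"]])}


def isometric_tension(state: np.ndarray, p: Parameters) -> float:
    _, out = rhs_py(0.0, state, p.vec)
    return float(out[OX["tension"]])


def set_sarcomere_stretch(p: Parameters, lam: float) -> Parameters:
    """Copy of ``p`` with the (fixed) sarcomere stretch ratio changed."""
    if lam <= 0:
        raise ValueError("stretch ratio must be positive")
    p2 = p.copy()
    p2.set("lam", lam)
    return p2
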