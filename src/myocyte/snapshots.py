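"""Shipped steady-state snapshots.

Snapshots are end-diastolic states produced by pacing the model to
convergence with `run_to_steady_state`; they seed simulations so that
protocols only need a short re-equilibration instead of a cold start.
"""

from __future__ import annotations

import importlib.resources as _res

import numpy as np

from .states import load_state, initial_state

_CACHE: dict[str, np.ndarray] = {}


def steady_state(preset: str = "male", rate_hz: float = 1.0,
                 bars: bool = False) -> np.ndarray:
    """Return a stored end-diastolic state for a baseline preset, or the
    generic initial state if no snapshot matches."""
    key = f"steady_{preset}_{rate_hz:g}hz" + ("_bars" if bars else "")
    if key not in _CACHE:
        path = _res.files("myocyte").joinpath(f"data/{key}.json")
        if path.is_file():
            with _res.as_file(path) as fp:
                _CACHE[key] = load_state(fp)
        else:
            _CACHE[key] = initial_state()
    return _CACHE[key].copy()
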