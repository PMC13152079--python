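"""Stochastic store-overload-dependent RyR release.

The deterministic model releases spontaneously only when SR load crosses the
regenerative threshold exactly; real diastolic release initiation is a
random event. This variant samples release-initiation events from an
inhomogeneous Poisson process whose hazard rises with SR calcium above a
threshold; between events the deterministic core is integrated unchanged
(the stiff solver never sees noise). An event opens a configurable fraction
of the calcium-sensitive RyR population, after which the deterministic
dynamics decide whether a full spontaneous release and DAD develops.

With ``rate_scale = 0`` the variant is exactly the deterministic model; with
a very large hazard above threshold it approaches the deterministic
overload-release limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SolverSettings, Trace, pace
from .parameters import Parameters
from .states import IX

__all__ = ["StochasticReleaseConfig", "simulate_stochastic"]


@dataclass
class StochasticReleaseConfig:
    seed: int = 0
    ca_sr_threshold: float = 1.9      # mM free SR calcium
    rate_scale: float = 2e-3          # hazard per ms per mM above threshold
    hazard_power: float = 2.0
    open_fraction: float = 0.25       # R -> O transfer at an event
    chunk_ms: float = 10.0            # hazard sampling resolution

    def hazard(self, ca_sr: float) -> float:
        x = ca_sr - self.ca_sr_threshold
        if x <= 0.0:
            return 0.0
        return self.rate_scale * x ** self.hazard_power


def _apply_event(y: np.ndarray, cfg: StochasticReleaseConfig) -> np.ndarray:
    y = y.copy()
    dr = cfg.open_fraction * y[IX["ryr_r"]]
    y[IX["ryr_r"]] -= dr
    y[IX["ryr_o"]] += dr
    return y


def simulate_stochastic(p: Parameters, bcl: float, n_beats: int,
                        cfg: StochasticReleaseConfig,
                        n_trials: int = 1, y0: np.ndarray | None = None,
                        tail_ms: float = 0.0,
                        settings: SolverSettings | None = None) -> dict:
    """Run ``n_trials`` independent realizations; returns per-trial traces
    and release-initiation event times (thinning algorithm on the hazard).
    """
    from .snapshots import steady_state
    rng_master = np.random.default_rng(cfg.seed)
    settings = settings or SolverSettings()
    trials = []
    for trial in range(n_trials):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        y = (y0 if y0 is not None else steady_state(p.sex)).copy()
        events = []
        traces = []
        t_offset = 0.0
        total = n_beats * bcl + tail_ms
        # integrate beat by beat; within each beat, walk in chunks and test
        # for a sampled event via thinning
        t_now = 0.0
        beat_edges = [b * bcl for b in range(n_beats)]
        while t_now < total - 1e-9:
            chunk = min(cfg.chunk_ms, total - t_now)
            # align chunks to beat boundaries so stimuli stay intact
            for be in beat_edges:
                if t_now < be < t_now + chunk:
                    chunk = be - t_now
                    break
            # sample a candidate release-initiation time on this chunk
            # (hazard held constant over the chunk)
            event_after = False
            if cfg.rate_scale > 0.0:
                lam = cfg.hazard(float(y[IX["ca_sr"]]))
                if lam > 0.0:
                    tau = rng.exponential(1.0 / lam)
                    if tau < chunk:
                        chunk = max(tau, 0.05)
                        event_after = True
            at_stim = any(abs(t_now - be) < 1e-9 for be in beat_edges)
            if at_stim:
                tr = pace(p, chunk, 1, y0=y, settings=settings)
            else:
                tr = _free_run(p, y, chunk, settings)
            y = tr._final
            if event_after:
                y = _apply_event(y, cfg)
                events.append(t_now + chunk)
            traces.append((t_now, tr))
            t_now += chunk
        ts, ys, outs = [], [], []
        for t0, tr in traces:
            tt = t0 + tr.t - tr.t[0]
            k = 1 if (ts and abs(ts[-1][-1] - tt[0]) < 1e-9) else 0
            ts.append(tt[k:])
            ys.append(tr.y[k:])
            outs.append(tr.out[k:])
        t_cat = np.concatenate(ts)
        y_cat = np.vstack(ys)
        out_cat = np.vstack(outs)
        trials.append({
            "trace": Trace(t_cat, y_cat, out_cat,
                           np.array(beat_edges)),
            "events": events,
        })
    n_ev = [len(tr["events"]) for tr in trials]
    return {"trials": trials, "n_events": n_ev,
            "mean_events": float(np.mean(n_ev))}


def _free_run(p: Parameters, y, duration, settings):
    # stimulus-free window with full recording
    from .model import _integrate_window
    import numpy as _np
    dt = settings.dt_sample
    te = _np.arange(0.0, duration + dt * 0.5, dt)
    te[-1] = min(te[-1], duration)
    sol = _integrate_window(p.vec, y, 0.0, duration, 0.0, settings, te, None)
    from ._kernel import rhs_py, N_OUT
    ys = sol.y.T
    out = _np.zeros((len(sol.t), N_OUT))
    for i in range(len(sol.t)):
        _, out[i] = rhs_py(sol.t[i], ys[i], p.vec)
    trace = Trace(sol.t, ys, out, _np.zeros(0))
    trace._final = sol.y[:, -1].copy()
    return trace
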