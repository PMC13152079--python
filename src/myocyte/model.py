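"""Pacing engine: stiff adaptive integration with stimulus event handling.

The integrator advances beat by beat; within a beat the stimulus window and
the free-running window are integrated separately so the solver never steps
over a discontinuity. Output is sampled on a uniform grid (default 0.5 ms)
for biomarker analysis; derived per-timepoint outputs (currents, fluxes,
tension) are recomputed from the state history through the same RHS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import states as st
from ._kernel import N_OUT, OX, rhs, rhs_py, _DUMMY_CLAMP
from .parameters import Parameters, P_INDEX

__all__ = ["SolverSettings", "Trace", "pace", "run_to_steady_state",
           "SteadyStateResult"]


@dataclass
class SolverSettings:
    rtol: float = 1e-7
    atol_conc: float = 1e-9
    atol_gate: float = 1e-8
    atol_v: float = 1e-6
    method: str = "LSODA"
    dt_sample: float = 0.5   # ms

    def atol_vector(self) -> np.ndarray:
        atol = np.full(st.N_STATES, self.atol_gate)
        atol[st.IX["v"]] = self.atol_v
        for n in st.CONC_NAMES:
            atol[st.IX[n]] = self.atol_conc
        for n in ("b_cam", "b_sll_sl", "b_slh_sl", "b_sll_d", "b_slh_d",
                  "b_csqn", "ca_trpn"):
            atol[st.IX[n]] = self.atol_conc
        return atol


@dataclass
class Trace:
    """Uniformly sampled time series of state plus derived outputs."""

    t: np.ndarray
    y: np.ndarray                       # (nt, N_STATES)
    out: np.ndarray                     # (nt, N_OUT)
    stim_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def state(self, name: str) -> np.ndarray:
        return self.y[:, st.IX[name]]

    def derived(self, name: str) -> np.ndarray:
        return self.out[:, OX[name]]

    @property
    def v(self) -> np.ndarray:
        return self.state("v")

    @property
    def ca_i(self) -> np.ndarray:
        return self.state("ca_myo")

    @property
    def tension(self) -> np.ndarray:
        return self.derived("tension")

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def beat_slice(self, beat: int) -> "Trace":
        """Sub-trace for one stimulus interval (0-based beat index)."""
        t0 = self.stim_times[beat]
        t1 = self.stim_times[beat + 1] if beat + 1 < len(self.stim_times) \
            else self.t[-1] + 1e-9
        m = (self.t >= t0 - 1e-9) & (self.t < t1)
        return Trace(self.t[m] - t0, self.y[m], self.out[m],
                     np.array([0.0]))


def _recompute_outputs(t, y, pvec, stim_times, stim_amp, stim_dur,
                       clamp=None) -> np.ndarray:
    out = np.empty((len(t), N_OUT))
    for i in range(len(t)):
        ist = 0.0
        for ts in stim_times:
            if ts <= t[i] < ts + stim_dur:
                ist = stim_amp
                break
        _, o = rhs_py(t[i], y[i], pvec, ist, clamp)
        out[i] = o
    return out


def _integrate_window(pvec, y0, t0, t1, istim, settings, t_eval, clamp):
    if clamp is None:
        flag, c0, cdt, cv = 0, 0.0, 1.0, _DUMMY_CLAMP
    else:
        flag, (c0, cdt, cv) = 1, clamp
    dy = np.zeros(st.N_STATES)
    out = np.zeros(N_OUT)

    def f(t, y):
        rhs(t, y, pvec, istim, flag, c0, cdt, cv, dy, out)
        return dy.copy()

    sol = solve_ivp(f, (t0, t1), y0, method=settings.method,
                    rtol=settings.rtol, atol=settings.atol_vector(),
                    t_eval=t_eval, dense_output=False,
                    max_step=(t1 - t0))
    if not sol.success:
        raise RuntimeError(
            f"solver failure at t={sol.t[-1] if len(sol.t) else t0:.3f} ms: "
            f"{sol.message}")
    return sol


def pace(p: Parameters, bcl: float, n_beats: int,
         y0: np.ndarray | None = None,
         settings: SolverSettings | None = None,
         record_from: int = 0,
         extra_tail: float = 0.0,
         clamp: tuple | None = None,
         stim_scale: float = 1.0) -> Trace:
    """Deliver ``n_beats`` stimuli at cycle length ``bcl`` (ms).

    Recording starts at beat ``record_from`` (earlier beats are integrated but
    not stored). ``extra_tail`` extends the recording window beyond the last
    cycle (diastolic monitoring for afterdepolarization assays).
    ``clamp=(t0, dt, v_array)`` activates AP-clamp mode; the stimulus is then
    irrelevant for V but retained for bookkeeping.
    """
    settings = settings or SolverSettings()
    pvec = p.vec
    y = (y0 if y0 is not None else st.initial_state()).copy()
    st.validate_state(y)
    amp = p["stim_amp"] * stim_scale
    dur = p["stim_dur"]
    dt = settings.dt_sample

    ts_list, ys_list = [], []
    stim_times = []
    t_now = 0.0
    for b in range(n_beats):
        record = b >= record_from
        if record:
            stim_times.append(t_now)  # stim annotations cover recorded beats
        # stimulus window
        n1 = max(2, int(round(dur / min(dt, 0.25))) + 1)
        te1 = np.linspace(t_now, t_now + dur, n1)
        sol1 = _integrate_window(pvec, y, t_now, t_now + dur, amp,
                                 settings, te1 if record else None, clamp)
        y = sol1.y[:, -1].copy()
        # free-running window
        te2 = np.arange(t_now + dur, t_now + bcl + dt * 0.5, dt)
        te2[0] = t_now + dur
        if te2[-1] > t_now + bcl:
            te2 = te2[:-1]
        sol2 = _integrate_window(pvec, y, t_now + dur, t_now + bcl, 0.0,
                                 settings, te2 if record else None, clamp)
        y = sol2.y[:, -1].copy()
        if record:
            # avoid duplicating the sample shared with the previous window
            k = 1 if (ts_list and abs(ts_list[-1][-1] - sol1.t[0]) < 1e-9) else 0
            ts_list.append(sol1.t[k:-1])
            ys_list.append(sol1.y[:, k:-1].T)
            ts_list.append(sol2.t)
            ys_list.append(sol2.y.T)
        t_now += bcl
    if extra_tail > 0:
        te3 = np.arange(t_now + dt, t_now + extra_tail + dt * 0.5, dt)
        sol3 = _integrate_window(pvec, y, t_now, t_now + extra_tail, 0.0,
                                 settings, te3, clamp)
        y = sol3.y[:, -1].copy()
        ts_list.append(sol3.t)
        ys_list.append(sol3.y.T)

    if ts_list:
        t_arr = np.concatenate(ts_list)
        y_arr = np.vstack(ys_list)
    else:  # zero beats recorded: trace holds the initial/final state only
        t_arr = np.array([t_now])
        y_arr = y[None, :]
    stim_arr = np.array(stim_times)
    out_arr = _recompute_outputs(t_arr, y_arr, pvec, stim_arr, amp, dur, clamp)
    tr = Trace(t_arr, y_arr, out_arr, stim_arr)
    tr._final = y  # final state even when recording was partial
    return tr


@dataclass
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    n_beats: int
    alternans: bool = False
    state_phase2: np.ndarray | None = None
    apd90: float = float("nan")
    apd90_phase2: float = float("nan")
    history: list = field(default_factory=list)


def _beat_apd90(t, v):
    """Cheap per-beat APD90 (shared logic with biomarkers.apd but local to
    avoid an import cycle)."""
    vrest = v[0]
    vmax = v.max()
    if vmax - vrest < 20.0:
        return float("nan")
    iup = int(np.argmax(np.diff(v)))
    thr = vrest + 0.1 * (vmax - vrest)
    for i in range(int(np.argmax(v)), len(v) - 1):
        if v[i] >= thr > v[i + 1]:
            frac = (v[i] - thr) / (v[i] - v[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]) - t[iup])
    return float("nan")


def run_to_steady_state(p: Parameters, rate_hz: float,
                        max_beats: int = 1000, tol: float = 1e-3,
                        y0: np.ndarray | None = None,
                        settings: SolverSettings | None = None,
                        check_every: int = 10) -> SteadyStateResult:
    """Pace until the beat-to-beat change of a monitored subset (diastolic V,
    bulk Na, diastolic SR Ca, APD90) falls below ``tol`` (relative, max-norm).

    A period-2 orbit (alternans) is detected by comparing to the state two
    beats back; in that case both phases are returned and flagged.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    settings = settings or SolverSettings()
    settings = SolverSettings(**{**settings.__dict__})
    settings.dt_sample = 1.0
    bcl = 1000.0 / rate_hz
    y = (y0 if y0 is not None else st.initial_state()).copy()
    prev = None
    prev2 = None
    hist = []
    y_prev_full = None
    for b in range(max_beats):
        tr = pace(p, bcl, 1, y0=y, settings=settings)
        y_prev2_full, y_prev_full = y_prev_full, y
        y = tr._final
        apd = _beat_apd90(tr.t, tr.v)
        mon = np.array([tr.v[-1], y[st.IX["na_myo"]], y[st.IX["ca_sr"]],
                        apd if np.isfinite(apd) else 0.0])
        hist.append(mon)
        if prev is not None and (b + 1) % check_every == 0:
            rel = np.abs(mon - prev) / (np.abs(prev) + 1e-12)
            if np.max(rel) < tol:
                return SteadyStateResult(y, True, b + 1, False, None,
                                         apd, history=hist)
            if prev2 is not None:
                rel2 = np.abs(mon - prev2) / (np.abs(prev2) + 1e-12)
                if np.max(rel2) < tol and np.max(rel) > 5 * tol:
                    return SteadyStateResult(
                        y, True, b + 1, True, y_prev_full, apd,
                        apd90_phase2=hist[-2][3], history=hist)
        prev2 = prev
        prev = mon
    return SteadyStateResult(y, False, max_beats, False, None,
                             hist[-1][3] if hist else float("nan"),
                             history=hist)
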