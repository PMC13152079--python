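"""Declarative protocol engine and the assays used for arrhythmia studies.

Every assay is a pure function of (Parameters, protocol settings): rerunning
with identical inputs yields identical results. Stimulation protocols follow
the conventions used throughout the results: steady pacing at a cycle
length, drug block as conductance multipliers, a two-level beta-adrenergic
switch, S1-S2 premature stimulation after a converged S1 train, and AP-clamp
pacing with a fixed waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .model import SolverSettings, Trace, pace, run_to_steady_state
from .parameters import Parameters, build_parameters
from .signaling import set_bars
from .snapshots import steady_state
from .states import IX

__all__ = ["Protocol", "run_protocol", "steady_pacing", "drug_panel",
           "ead_assay", "ead_threshold_scan", "dad_assay", "alternans_assay",
           "ap_clamp_alternans", "ap_clamp_waveform", "s1s2_restitution",
           "apd_vs_slope_study", "rate_sweep", "FIG1E_DRUGS"]

# drug panel: block fractions for channel-blocking drugs at reference doses
FIG1E_DRUGS: dict[str, dict[str, float]] = {
    "E-4031":     {"IKr": 0.30},
    "HMR-1556":   {"IKs": 0.10},
    "nisoldipine": {"ICaL": 0.10},
    "mexiletine": {"INaL": 0.46, "IKr": 0.91, "ICaL": 0.80},
}


@dataclass
class Protocol:
    """Declarative description of a stimulation experiment."""

    kind: str = "steady_pacing"
    rate_hz: float | None = 1.0
    bcl_ms: float | None = None
    n_beats: int = 100
    record_last: int = 2
    drug_block: dict = field(default_factory=dict)
    bars: bool = False
    cao: float | None = None
    s1_ms: float = 1000.0
    n_s1: int = 20
    s2_list: list = field(default_factory=list)
    rates: list = field(default_factory=list)
    bcls: list = field(default_factory=list)
    serca_mult: float = 1.0
    tail_ms: float = 0.0

    def __post_init__(self):
        if self.bcl_ms is None and self.rate_hz:
            self.bcl_ms = 1000.0 / self.rate_hz
        if self.bcl_ms is not None and self.bcl_ms <= 0:
            raise ValueError("cycle length must be positive")
        for k, v in self.drug_block.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"block fraction for {k} outside [0, 1]")
        if self.s2_list and list(self.s2_list) != sorted(self.s2_list):
            raise ValueError("S2 interval list must be strictly increasing")

    @property
    def multipliers(self) -> dict:
        """Pore-block model: remaining-fraction multipliers."""
        return {k: 1.0 - v for k, v in self.drug_block.items()}


def _prepare(p: Parameters, proto: Protocol) -> Parameters:
    q = p.with_multipliers(proto.multipliers) if proto.multipliers else p.copy()
    if proto.serca_mult != 1.0:
        q = q.with_multipliers({"SERCA": proto.serca_mult})
    if proto.cao is not None:
        q.set("cao", proto.cao)
    if proto.bars:
        q = set_bars(q, True)
    return q


def run_protocol(p: Parameters, proto: Protocol,
                 s0: np.ndarray | None = None,
                 settings: SolverSettings | None = None):
    """Dispatch a declarative protocol. Returns a Trace for pacing/clamp
    kinds and a result object/DataFrame for composite assays."""
    if proto.kind == "steady_pacing":
        return steady_pacing(p, proto, s0, settings)
    if proto.kind == "drug_panel":
        return drug_panel(p, rates=proto.rates or (0.5, 1.0, 2.0),
                          n_beats=proto.n_beats, s0=s0)
    if proto.kind == "ead_assay":
        mult = proto.multipliers
        return ead_assay(p, rate_hz=proto.rate_hz or 0.25,
                         ikr_mult=mult.get("IKr", 0.15),
                         ical_mult=mult.get("ICaL", 1.0),
                         n_beats=proto.n_beats, s0=s0)
    if proto.kind == "dad_assay":
        return dad_assay(p, rate_hz=proto.rate_hz or 2.5,
                         n_beats=proto.n_beats, bars=proto.bars,
                         cao=proto.cao or 3.25,
                         tail_ms=proto.tail_ms or 5000.0, s0=s0)
    if proto.kind == "alternans_assay":
        return alternans_assay(p, bcls=proto.bcls, n_beats=proto.n_beats,
                               serca_mult=proto.serca_mult, bars=proto.bars,
                               s0=s0)
    if proto.kind == "ap_clamp":
        return ap_clamp_alternans(p, bcl=proto.bcl_ms or 240.0,
                                  n=proto.n_beats, s0=s0)
    if proto.kind == "s1s2_restitution":
        return s1s2_restitution(p, s1=proto.s1_ms, n_s1=proto.n_s1,
                                s2_list=proto.s2_list or None, s0=s0)
    if proto.kind == "rate_sweep":
        return rate_sweep(p, rates=proto.rates or (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
                          s0=s0)
    raise ValueError(f"unknown protocol kind: {proto.kind!r}")


def steady_pacing(p: Parameters, proto: Protocol,
                  s0: np.ndarray | None = None,
                  settings: SolverSettings | None = None) -> Trace:
    q = _prepare(p, proto)
    y0 = s0 if s0 is not None else steady_state(p.sex)
    if proto.n_beats == 0:
        return pace(q, proto.bcl_ms, 0, y0=y0, settings=settings)
    rec = max(0, proto.n_beats - proto.record_last)
    return pace(q, proto.bcl_ms, proto.n_beats, y0=y0, record_from=rec,
                settings=settings, extra_tail=proto.tail_ms)


# ---------------------------------------------------------------------- drugs
def drug_panel(p: Parameters, drugs: dict | None = None,
               rates=(0.5, 1.0, 2.0), n_beats: int = 150,
               s0: np.ndarray | None = None) -> pd.DataFrame:
    """Steady-state APD90 for each drug x pacing rate, plus baseline."""
    drugs = FIG1E_DRUGS if drugs is None else drugs
    rows = []
    for rate in rates:
        bcl = 1000.0 / rate
        for name, block in [("baseline", {})] + list(drugs.items()):
            q = p.with_multipliers({k: 1.0 - v for k, v in block.items()})
            y0 = s0 if s0 is not None else steady_state(p.sex)
            tr = pace(q, bcl, n_beats, y0=y0, record_from=n_beats - 1)
            rows.append({"drug": name, "rate_hz": rate,
                         "apd90": bm.apd(tr, 0)})
    df = pd.DataFrame(rows)
    base = df[df.drug == "baseline"].set_index("rate_hz")["apd90"]
    df["delta_apd90"] = df.apply(
        lambda r: r.apd90 - base.loc[r.rate_hz], axis=1)
    return df


# ----------------------------------------------------------------------- EADs
def ead_assay(p: Parameters, rate_hz: float = 0.25, ikr_mult: float = 0.15,
              ical_mult: float = 1.0, n_beats: int = 10,
              s0: np.ndarray | None = None,
              cfg: bm.DetectorConfig | None = None) -> dict:
    """Pace slowly under IKr block and count early afterdepolarizations on
    the final beat."""
    mult = {"IKr": ikr_mult}
    if ical_mult != 1.0:
        mult["ICaL"] = ical_mult
    q = p.with_multipliers(mult)
    y0 = s0 if s0 is not None else steady_state(p.sex)
    bcl = 1000.0 / rate_hz
    tr = pace(q, bcl, n_beats, y0=y0, record_from=n_beats - 1)
    b = tr.beat_slice(0)
    events = bm.detect_eads(b.t, b.v, cfg)
    return {"ead_count": len(events),
            "amplitudes": [a for _, a in events],
            "ead_amplitude": max((a for _, a in events), default=np.nan),
            "apd90": bm.apd(tr, 0), "trace": tr}


def ead_threshold_scan(p: Parameters, ikr_multipliers=None,
                       rate_hz: float = 0.25, n_beats: int = 10,
                       ical_mult: float = 1.0,
                       s0: np.ndarray | None = None) -> pd.DataFrame:
    """APD and EAD count across IKr availability; the first multiplier (from
    above) with an EAD marks the vulnerability threshold."""
    if ikr_multipliers is None:
        ikr_multipliers = np.round(np.arange(1.0, 0.049, -0.05), 3)
    rows = []
    for mult in ikr_multipliers:
        r = ead_assay(p, rate_hz=rate_hz, ikr_mult=float(mult),
                      ical_mult=ical_mult, n_beats=n_beats, s0=s0)
        b = r["trace"].beat_slice(0)
        # APD at the last repolarization within the window (EAD beats repolarize late)
        apd = r["apd90"]
        if np.isnan(apd):
            apd = 1000.0 / rate_hz  # failed repolarization: full cycle
        rows.append({"ikr_mult": float(mult), "apd90": apd,
                     "ead_count": r["ead_count"],
                     "ead_amplitude": r["ead_amplitude"]})
    df = pd.DataFrame(rows)
    hit = df[df.ead_count > 0]
    df.attrs["first_ead_multiplier"] = float(hit.ikr_mult.max()) if len(hit) \
        else np.nan
    return df


# ----------------------------------------------------------------------- DADs
def dad_assay(p: Parameters, rate_hz: float = 2.5, n_beats: int = 200,
              bars: bool = True, cao: float = 3.25,
              tail_ms: float = 5000.0, s0: np.ndarray | None = None,
              cfg: bm.DetectorConfig | None = None) -> dict:
    """Rapid prepacing under calcium loading, then a diastolic observation
    window: spontaneous SR release drives NCX inward current and delayed
    afterdepolarizations, possibly triggering full APs."""
    q = p.copy()
    q.set("cao", cao)
    if bars:
        q = set_bars(q, True)
    y0 = s0 if s0 is not None else steady_state(p.sex)
    bcl = 1000.0 / rate_hz
    tr = pace(q, bcl, n_beats, y0=y0, record_from=max(0, n_beats - 3),
              extra_tail=tail_ms)
    # diastolic window: from repolarization of the final paced beat (the
    # beat's own upstroke must be skipped before searching)
    t_last = tr.stim_times[-1]
    m = tr.t > t_last
    t, v = tr.t[m], tr.v[m]
    up = np.flatnonzero(v > -20.0)
    i_up = up[0] if len(up) else 0
    rep = np.flatnonzero(v[i_up:] < -75.0)
    if len(rep) == 0:
        return {"dads": [], "triggered": [], "trace": tr,
                "note": "no repolarization in observation window"}
    i0 = i_up + rep[0]
    dads, trig = bm.detect_dads(t[i0:], v[i0:], cfg)
    return {"dads": dads, "triggered": trig, "trace": tr,
            "ca_sr_tail": tr.y[m, IX["ca_sr"]][i0:], "t_tail": t[i0:]}


# ------------------------------------------------------------------ alternans
def _per_beat_series(tr: Trace, n: int):
    apds, amps = [], []
    for b in range(n):
        try:
            bb = tr.beat_slice(b)
        except IndexError:
            break
        apds.append(bm.apd(tr, b))
        ca = bb.state("ca_myo")
        amps.append(float(ca.max() - ca[0]))
    return np.array(apds), np.array(amps)


def alternans_assay(p: Parameters, bcls, n_beats: int = 120,
                    record_last: int = 24, serca_mult: float = 1.0,
                    bars: bool = False, s0: np.ndarray | None = None,
                    cfg: bm.DetectorConfig | None = None) -> pd.DataFrame:
    """Beat-to-beat APD and CaT-amplitude alternation at each cycle length.

    Alternans magnitude is |mean(odd) - mean(even)| over the recorded tail;
    the concordance flag records whether long APD coincides with large CaT."""
    cfg = cfg or bm.DetectorConfig()
    rows = []
    for bcl in bcls:
        q = p.copy()
        if serca_mult != 1.0:
            q = q.with_multipliers({"SERCA": serca_mult})
        if bars:
            q = set_bars(q, True)
        y0 = s0 if s0 is not None else steady_state(p.sex)
        tr = pace(q, float(bcl), n_beats, y0=y0,
                  record_from=n_beats - record_last)
        apds, amps = _per_beat_series(tr, record_last)
        d_apd, s_apd = bm.alternans_magnitude(apds, record_last)
        d_cat, s_cat = bm.alternans_magnitude(amps, record_last)
        captured = np.isfinite(apds).all() and np.nanmin(apds) > 0
        rows.append({
            "bcl": float(bcl), "delta_apd": d_apd, "delta_cat": d_cat,
            "cat_mean": float(np.nanmean(amps)),
            "alternans": bool(d_apd > cfg.alternans_apd_ms
                              or d_cat > cfg.alternans_cat_frac
                              * np.nanmean(amps)),
            "concordant": bool(s_apd == s_cat) if d_apd > 0 and d_cat > 0
            else True,
            "captured": bool(captured),
        })
    return pd.DataFrame(rows)


def ap_clamp_waveform(p: Parameters, bcl: float = 240.0,
                      s0: np.ndarray | None = None,
                      dt: float = 0.5) -> tuple[float, float, np.ndarray]:
    """Fixed-shape AP waveform for clamp mode: the steady-state baseline AP
    resampled at ``dt`` ms, held at resting potential between applications,
    truncated to the clamp cycle length."""
    y0 = s0 if s0 is not None else steady_state(p.sex)
    tr = pace(p, 1000.0, 3, y0=y0, record_from=2,
              settings=SolverSettings(dt_sample=dt))
    b = tr.beat_slice(0)
    v = b.v.copy()
    n = int(round(bcl / dt))
    vrest = v[0]
    amp = v.max() - vrest
    w = v[:n].copy() if len(v) >= n else np.concatenate(
        [v, np.full(n - len(v), vrest)])
    # hold at resting potential once repolarized; if the source AP outlasts
    # the clamp cycle, terminate it with a brief ramp so the clamped cell
    # retains a diastolic interval
    below = np.flatnonzero(w < vrest + 0.02 * amp)
    start = int(np.argmax(w))
    below = below[below > start]
    if len(below):
        w[below[0]:] = vrest
    else:
        n_dia = max(4, int(round(0.20 * n)))     # >= 20% of the cycle diastolic
        n_ramp = max(2, int(round(10.0 / dt)))
        i0 = n - n_dia - n_ramp
        w[i0:i0 + n_ramp] = np.linspace(w[i0], vrest, n_ramp)
        w[i0 + n_ramp:] = vrest
    return (0.0, dt, w)


def ap_clamp_alternans(p: Parameters, waveform=None, bcl: float = 240.0,
                       n: int = 250, record_last: int = 24,
                       s0: np.ndarray | None = None) -> dict:
    """Calcium alternans under a fixed AP shape: isolates the calcium-handling
    oscillation from AP-restitution feedback."""
    if waveform is None:
        waveform = ap_clamp_waveform(p, bcl, s0)
    t0, dt, w = waveform
    nrep = int(round(bcl / dt))
    full = np.tile(w[:nrep], n)
    y0 = (s0 if s0 is not None else steady_state(p.sex)).copy()
    y0[IX["v"]] = full[0]
    tr = pace(p, bcl, n, y0=y0, record_from=n - record_last,
              clamp=(0.0, dt, full))
    apds, amps = _per_beat_series(tr, record_last)
    d_cat, _ = bm.alternans_magnitude(amps, record_last)
    return {"delta_cat": d_cat, "cat_mean": float(np.nanmean(amps)),
            "alternans": bool(d_cat > 0.05 * np.nanmean(amps)),
            "trace": tr, "waveform": (0.0, dt, full)}


# ----------------------------------------------------------------- restitution
def s1s2_restitution(p: Parameters, s1: float = 1000.0, n_s1: int = 20,
                     s2_list=None, s0: np.ndarray | None = None) -> dict:
    """APD90 of a premature S2 beat against its coupling interval after a
    converged S1 train; the reported slope is the maximum centered finite
    difference along the curve."""
    if s2_list is None:
        s2_list = np.concatenate([
            np.arange(250.0, 400.0, 10.0),
            np.arange(400.0, 700.0, 25.0),
            np.arange(700.0, 1101.0, 50.0)])
    s2_list = np.asarray(sorted(s2_list), dtype=float)
    y0 = s0 if s0 is not None else steady_state(p.sex)
    # S1 train up to the onset of the final S1 beat
    tr = pace(p, s1, n_s1 - 1, y0=y0, record_from=n_s1 - 2)
    y_pre = tr._final          # end of the (n_s1 - 1)th cycle
    apd_ss = bm.apd(tr, 0)
    rows = []
    for s2 in s2_list:
        # final S1 beat truncated at the S2 coupling interval, then the
        # premature S2 beat itself, recorded
        tr1 = pace(p, float(s2), 1, y0=y_pre.copy(), record_from=1)
        tr2 = pace(p, max(1000.0, float(s2)), 1, y0=tr1._final,
                   record_from=0, extra_tail=500.0)
        apd2 = bm.apd(tr2, 0)
        bb = tr2.beat_slice(0)
        captured = bool(np.isfinite(apd2) and bb.v.max() > 0.0
                        and apd2 > 40.0)
        di = s2 - apd_ss
        rows.append({"s2": float(s2), "di": float(di), "apd90": apd2,
                     "captured": captured})
    df = pd.DataFrame(rows)
    ok = df[df.captured & np.isfinite(df.apd90)] \
        .drop_duplicates(subset="s2").reset_index(drop=True)
    slope = np.nan
    sl_at = np.nan
    if len(ok) >= 3:
        s = ok.s2.to_numpy()
        a = ok.apd90.to_numpy()
        dslope = np.gradient(a, s)
        k = int(np.argmax(dslope))
        slope = float(dslope[k])
        sl_at = float(s[k])
    return {"curve": df, "max_slope": slope, "s2_at_max_slope": sl_at,
            "apd_ss": apd_ss}


def apd_vs_slope_study(param_sets, s1: float = 1000.0, n_s1: int = 20,
                       s0=None, s2_list=None) -> pd.DataFrame:
    """Steady-state APD against maximum S1-S2 restitution slope for a
    collection of parameter sets (e.g. conductance-varied variants)."""
    rows = []
    for i, q in enumerate(param_sets):
        r = s1s2_restitution(q, s1=s1, n_s1=n_s1, s0=s0, s2_list=s2_list)
        rows.append({"model": i, "apd_ss": r["apd_ss"],
                     "max_slope": r["max_slope"]})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ rate sweep
def rate_sweep(p: Parameters, rates=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
               max_beats: int = 400, tol: float = 1e-3,
               s0: np.ndarray | None = None) -> pd.DataFrame:
    """Steady-state rate dependence of peak systolic calcium, peak active
    tension and diastolic SR calcium, normalized to the 0.5 Hz values (%)."""
    rows = []
    for rate in rates:
        y0 = s0 if s0 is not None else steady_state(p.sex)
        ss = run_to_steady_state(p, rate, max_beats=max_beats, tol=tol, y0=y0)
        tr = pace(p, 1000.0 / rate, 2, y0=ss.state, record_from=1)
        b = tr.beat_slice(0)
        rows.append({
            "rate_hz": float(rate),
            "cat_peak": float(b.state("ca_myo").max()),
            "cat_amp": float(b.state("ca_myo").max() - b.state("ca_myo")[0]),
            "tension_peak": float(b.tension.max()),
            "ca_sr_dia": float(b.state("ca_sr")[0]),
            "apd90": bm.apd(tr, 0),
            "alternans": ss.alternans,
        })
    df = pd.DataFrame(rows)
    ref = df[df.rate_hz == min(rates)].iloc[0]
    df["cat_peak_pct"] = 100.0 * df.cat_peak / ref.cat_peak
    df["tension_peak_pct"] = 100.0 * df.tension_peak / ref.tension_peak
    df["ca_sr_pct"] = 100.0 * df.ca_sr_dia / ref.ca_sr_dia
    return df
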