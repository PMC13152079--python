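"""Per-beat biomarkers and arrhythmia-event detectors.

Conventions
-----------
* APD at level L: time from the instant of maximum upstroke velocity to the
  downward crossing of ``V_rest + (1 - L/100) * AP_amplitude``, linearly
  interpolated between samples.
* CaT duration at L% recovery: from CaT onset-peak, time until the transient
  has recovered L% of its amplitude.
* EAD: an episode of positive dV/dt beginning more than ``ead_min_delay`` ms
  after the upstroke, at V above ``ead_vmin`` mV, before full repolarization.
* DAD: diastolic depolarization exceeding ``dad_threshold`` mV above the
  post-repolarization baseline without a stimulus; a triggered AP is a
  crossing of ``trigger_v`` with regenerative upstroke and is not
  double-counted as a DAD.

Thresholds are config-exposed via :class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Trace

__all__ = ["DetectorConfig", "BiomarkerSet", "apd", "cat_metrics",
           "tension_biomarkers", "beat_biomarkers", "clearance_fractions",
           "detect_eads", "detect_dads", "alternans_magnitude"]


@dataclass
class DetectorConfig:
    ead_min_delay: float = 100.0   # ms after upstroke
    ead_vmin: float = -40.0        # mV
    ead_min_amp: float = 0.5       # mV prominence for counting
    dad_threshold: float = 1.0     # mV above diastolic baseline
    trigger_v: float = -40.0       # mV, triggered-AP crossing
    alternans_apd_ms: float = 3.0  # significance threshold
    alternans_cat_frac: float = 0.05
    repol_level: float = 90.0


@dataclass
class BiomarkerSet:
    """Scalar outputs for one analyzed beat."""

    apd90: float = np.nan
    apd50: float = np.nan
    v_rest: float = np.nan
    v_peak: float = np.nan
    dvdt_max: float = np.nan
    cat_amplitude: float = np.nan
    cat_diastolic: float = np.nan
    cat_ttp: float = np.nan
    catd50: float = np.nan
    catd90: float = np.nan
    tension_peak: float = np.nan
    tension_ttp: float = np.nan
    tension_rt95: float = np.nan
    ca_sr_diastolic: float = np.nan
    ead_count: int = 0
    ead_amplitude: float = np.nan
    repolarized: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _upstroke_index(t: np.ndarray, v: np.ndarray) -> int:
    dv = np.diff(v) / np.diff(t)
    return int(np.argmax(dv))


def _cross_down(t, x, thr, start):
    for i in range(start, len(x) - 1):
        if x[i] >= thr > x[i + 1]:
            frac = (x[i] - thr) / (x[i] - x[i + 1])
            return t[i] + frac * (t[i + 1] - t[i])
    return np.nan


def apd(trace: Trace, beat: int = 0, level: float = 90.0) -> float:
    """Action-potential duration (ms) at the given repolarization level.

    Returns NaN when the beat fails to repolarize before the next stimulus
    (EAD / failed-repolarization pathway -- flagged, not an error).
    """
    b = trace.beat_slice(beat) if len(trace.stim_times) > 1 or beat > 0 \
        else trace
    t, v = b.t, b.v
    iu = _upstroke_index(t, v)
    vrest = v[0]
    vamp = v.max() - vrest
    if vamp < 10.0:
        return np.nan
    thr = vrest + (1.0 - level / 100.0) * vamp
    tc = _cross_down(t, v, thr, int(np.argmax(v)))
    if np.isnan(tc):
        return np.nan
    return float(tc - t[iu])


def cat_metrics(t, ca, upstroke_t=0.0):
    """Diastolic level, amplitude, time to peak and recovery durations of a
    calcium transient given on a (time, concentration) grid."""
    dia = float(ca[0])
    ipk = int(np.argmax(ca))
    peak = float(ca[ipk])
    amp = peak - dia
    ttp = float(t[ipk] - upstroke_t)
    if amp <= 0:
        return dia, 0.0, np.nan, np.nan, np.nan
    d50 = _cross_down(t, ca, peak - 0.5 * amp, ipk)
    d90 = _cross_down(t, ca, peak - 0.9 * amp, ipk)
    return dia, amp, ttp, float(d50 - upstroke_t) if not np.isnan(d50) else np.nan, \
        float(d90 - upstroke_t) if not np.isnan(d90) else np.nan


def tension_biomarkers(trace: Trace, beat: int = 0) -> dict:
    """Peak active tension (kPa), time to peak, and time from peak to 95%
    recovery of the transient."""
    b = trace.beat_slice(beat)
    t, ta = b.t, b.tension
    base = float(ta[0])
    ipk = int(np.argmax(ta))
    peak = float(ta[ipk])
    amp = peak - base
    if amp <= 0:
        return {"tension_peak": peak, "tension_ttp": np.nan,
                "tension_rt95": np.nan}
    t95 = _cross_down(t, ta, peak - 0.95 * amp, ipk)
    return {"tension_peak": peak, "tension_ttp": float(t[ipk] - t[0]),
            "tension_rt95": float(t95 - t[ipk]) if not np.isnan(t95) else np.nan}


def detect_eads(t, v, cfg: DetectorConfig | None = None):
    """Return a list of (time, amplitude) of EADs within one beat."""
    cfg = cfg or DetectorConfig()
    iu = _upstroke_index(t, v)
    vrest = v[0]
    vamp = v.max() - vrest
    thr_repol = vrest + 0.1 * vamp
    dv = np.gradient(v, t)
    events = []
    i = iu
    n = len(t)
    while i < n - 1:
        if (t[i] - t[iu] > cfg.ead_min_delay and v[i] > cfg.ead_vmin
                and v[i] > thr_repol and dv[i] > 0.0 and dv[i - 1] <= 0.0):
            # local minimum at i; find following local max
            jmax = i
            while jmax < n - 1 and v[jmax + 1] >= v[jmax]:
                jmax += 1
            amp = v[jmax] - v[i]
            if amp >= cfg.ead_min_amp:
                events.append((float(t[jmax]), float(amp)))
            i = jmax + 1
        else:
            i += 1
    return events


def detect_dads(t, v, cfg: DetectorConfig | None = None):
    """Detect diastolic events after the final repolarization.

    Returns (dad_events, triggered_ap_times); each DAD event is
    (time_of_peak, amplitude above baseline). Input should be a diastolic
    window beginning after repolarization of the last paced beat.
    """
    cfg = cfg or DetectorConfig()
    base = np.min(v)
    events = []
    triggered = []
    above = v > cfg.trigger_v
    i = 1
    n = len(t)
    while i < n - 1:
        if above[i] and not above[i - 1]:
            # regenerative if the depolarization overshoots well beyond the
            # crossing (full AP), or rises steeply at the crossing
            j = i
            while j < n - 1 and v[j + 1] >= v[j]:
                j += 1
            dv = (v[i + 1] - v[i - 1]) / (t[i + 1] - t[i - 1])
            if v[j] > -10.0 or dv > 1.0:
                triggered.append(float(t[i]))
                i = j
                while i < n - 1 and v[i] > base + 0.5 * cfg.dad_threshold:
                    i += 1
                continue
        i += 1
    # sub-threshold depolarizations (exclude triggered-AP intervals)
    dv = np.gradient(v, t)
    i = 1
    while i < n - 1:
        if dv[i - 1] > 0 >= dv[i] and v[i] < cfg.trigger_v:
            amp = v[i] - base
            if amp >= cfg.dad_threshold:
                near_ap = any(abs(t[i] - ta) < 50.0 for ta in triggered)
                if not near_ap:
                    events.append((float(t[i]), float(amp)))
        i += 1
    return events, triggered


def beat_biomarkers(trace: Trace, beat: int = 0,
                    cfg: DetectorConfig | None = None) -> BiomarkerSet:
    cfg = cfg or DetectorConfig()
    b = trace.beat_slice(beat)
    t, v = b.t, b.v
    iu = _upstroke_index(t, v)
    bm = BiomarkerSet()
    bm.v_rest = float(v[0])
    bm.v_peak = float(v.max())
    dv = np.diff(v) / np.diff(t)
    bm.dvdt_max = float(dv.max())
    bm.apd90 = apd(trace, beat, 90.0)
    bm.apd50 = apd(trace, beat, 50.0)
    bm.repolarized = not np.isnan(bm.apd90)
    ca = b.state("ca_myo")
    dia, amp, ttp, d50, d90 = cat_metrics(t, ca, t[iu])
    bm.cat_diastolic = dia
    bm.cat_amplitude = amp
    bm.cat_ttp = ttp
    bm.catd50 = d50
    bm.catd90 = d90
    bm.ca_sr_diastolic = float(b.state("ca_sr")[0])
    bm.__dict__.update(tension_biomarkers(trace, beat))
    eads = detect_eads(t, v, cfg)
    bm.ead_count = len(eads)
    bm.ead_amplitude = max(a for _, a in eads) if eads else np.nan
    return bm


def clearance_fractions(trace: Trace, beat: int = 0) -> dict:
    """Partition cytosolic calcium removal during the CaT decay between
    SERCA uptake, forward-mode NCX extrusion and the sarcolemmal calcium
    pump.

    Fluxes are integrated (trapezoid) on the dense output between the CaT
    peak and 95% recovery of the transient; fractions are normalized to the
    three-pathway total.
    """
    b = trace.beat_slice(beat)
    t = b.t
    ca = b.state("ca_myo")
    dia = ca[0]
    ipk = int(np.argmax(ca))
    amp = ca[ipk] - dia
    t95 = _cross_down(t, ca, ca[ipk] - 0.95 * amp, ipk)
    if np.isnan(t95):
        t95 = t[-1]
    m = (t >= t[ipk]) & (t <= t95)
    tt = t[m]
    jup = np.trapezoid(b.derived("jup")[m], tt)
    jncx = np.trapezoid(np.clip(-b.derived("jncx_ca")[m], 0.0, None), tt)
    jpca = np.trapezoid(np.clip(-b.derived("jpca_ca")[m], 0.0, None), tt)
    tot = jup + jncx + jpca
    return {"SERCA": jup / tot, "NCX": jncx / tot, "pCa": jpca / tot,
            "total_mM": tot}


def alternans_magnitude(values: np.ndarray, last_n: int = 20):
    """Mean absolute odd/even split of a per-beat series (APD or CaT
    amplitude) over its final ``last_n`` entries, plus the phase sign."""
    x = np.asarray(values, dtype=float)[-last_n:]
    x = x[np.isfinite(x)]
    if len(x) < 4:
        return 0.0, 0.0
    odd = x[1::2].mean()
    even = x[0::2].mean()
    return float(abs(odd - even)), float(np.sign(odd - even))
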