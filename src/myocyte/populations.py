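"""Population-of-models generation, calibration filtering, and
arrhythmia-susceptibility scans.

A population is built by sampling independent uniform multipliers on key
ionic currents and fluxes (default range 0.67-1.50), pacing each variant to
quasi-steady state at 1 Hz, and keeping the variants whose biomarkers fall
inside human calibration intervals. Susceptibility scans then ask whether
each calibrated variant can manifest EADs, DADs, alternans or steep S1-S2
restitution under standard provocations, using early-exit evaluation (the
strongest provocation is tried first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .model import pace
from .parameters import Parameters, POPULATION_TARGETS, build_parameters
from .protocols import alternans_assay, ead_assay, dad_assay, s1s2_restitution
from .snapshots import steady_state

__all__ = ["PopulationSpec", "CalibrationCriteria", "sample_population",
           "calibrate", "ead_capability_scan", "dad_threshold_scan",
           "alternans_capability_scan", "restitution_slope_scan"]


@dataclass
class PopulationSpec:
    targets: list = field(default_factory=lambda: list(POPULATION_TARGETS))
    low: float = 0.67
    high: float = 1.50
    size: int = 100
    seed: int = 0
    distribution: str = "uniform"   # or "loguniform"
    preset: str = "male"

    def __post_init__(self):
        if self.low <= 0 or self.high <= 0 or self.low >= self.high:
            raise ValueError("multiplier range bounds must satisfy 0 < low < high")
        if self.size < 1:
            raise ValueError("population size must be >= 1")


@dataclass
class CalibrationCriteria:
    """Biomarker acceptance intervals derived from human data (1 Hz).

    Intervals follow the experimental ranges used to constrain the baseline:
    APD and resting potential from human ventricular AP recordings, CaT
    amplitude/kinetics from human trabeculae, tension from human myocardium.
    """

    intervals: dict = field(default_factory=lambda: {
        "apd90": (180.0, 440.0),
        "v_rest": (-95.0, -80.0),
        "dvdt_max": (60.0, 1000.0),
        "cat_amplitude": (1.45e-4, 1.36e-3),
        "cat_diastolic": (2.0e-5, 3.2e-4),
        "catd90": (220.0, 785.0),
        "cat_ttp": (5.0, 120.0),
        "tension_peak": (5.0, 95.0),
        "ca_sr_diastolic": (0.5, 4.0),
    })

    def __post_init__(self):
        for k, (lo, hi) in self.intervals.items():
            if lo >= hi:
                raise ValueError(f"criterion {k}: lower bound must be < upper")

    def check(self, biom: bm.BiomarkerSet) -> list:
        """Names of violated criteria (empty = accepted)."""
        bad = []
        d = biom.as_dict()
        for k, (lo, hi) in self.intervals.items():
            v = d.get(k, np.nan)
            if not np.isfinite(v) or not (lo <= v <= hi):
                bad.append(k)
        return bad


def sample_population(spec: PopulationSpec) -> list[Parameters]:
    """Deterministic under fixed seed; multipliers within the declared range."""
    rng = np.random.default_rng(spec.seed)
    models = []
    for i in range(spec.size):
        if spec.distribution == "uniform":
            mults = rng.uniform(spec.low, spec.high, size=len(spec.targets))
        elif spec.distribution == "loguniform":
            mults = np.exp(rng.uniform(np.log(spec.low), np.log(spec.high),
                                       size=len(spec.targets)))
        else:
            raise ValueError(f"unknown distribution {spec.distribution!r}")
        m = {t: float(f) for t, f in zip(spec.targets, mults)}
        models.append(build_parameters(spec.preset, m))
    return models


def _steady_biomarkers(q: Parameters, n_beats: int, s0) -> bm.BiomarkerSet:
    y0 = s0 if s0 is not None else steady_state(q.sex)
    tr = pace(q, 1000.0, n_beats, y0=y0, record_from=n_beats - 1)
    return bm.beat_biomarkers(tr)


def calibrate(models: list[Parameters],
              criteria: CalibrationCriteria | None = None,
              n_beats: int = 60, s0=None) -> dict:
    """Pace each variant at 1 Hz and filter on the acceptance intervals.

    Returns accepted models, the acceptance mask, and per-criterion failure
    counts."""
    criteria = criteria or CalibrationCriteria()
    accepted, mask = [], []
    failures: dict[str, int] = {k: 0 for k in criteria.intervals}
    rows = []
    for q in models:
        try:
            biom = _steady_biomarkers(q, n_beats, s0)
            bad = criteria.check(biom)
        except Exception:
            bad = ["integration_failure"]
            failures.setdefault("integration_failure", 0)
            biom = bm.BiomarkerSet()
        for k in bad:
            failures[k] = failures.get(k, 0) + 1
        ok = not bad
        mask.append(ok)
        if ok:
            accepted.append(q)
        rows.append({**biom.as_dict(), "accepted": ok})
    return {"accepted": accepted, "mask": np.array(mask),
            "failure_counts": failures,
            "fraction": float(np.mean(mask)) if models else np.nan,
            "biomarkers": pd.DataFrame(rows)}


# ------------------------------------------------------------------ scans
def ead_capability_scan(models, ikr_grid=None, ical_grid=None,
                        n_beats: int = 8, s0=None) -> pd.DataFrame:
    """Minimal pro-EAD perturbation (IKr down, ICaL up) per model on a fixed
    grid; evaluated strongest-first so capable models need one simulation."""
    if ikr_grid is None:
        ikr_grid = np.round(np.arange(1.0, 0.09, -0.1), 2)
    if ical_grid is None:
        ical_grid = np.round(np.arange(1.0, 2.01, 0.25), 2)
    # order perturbations from strongest to weakest
    combos = sorted(
        ((ikr, ical) for ikr in ikr_grid for ical in ical_grid),
        key=lambda c: (c[0], -c[1]))
    rows = []
    for i, q in enumerate(models):
        hit = None
        for ikr, ical in combos:
            r = ead_assay(q, ikr_mult=float(ikr), ical_mult=float(ical),
                          n_beats=n_beats, s0=s0)
            if r["ead_count"] > 0:
                hit = (ikr, ical)
                break
        rows.append({"model": i, "capable": hit is not None,
                     "ikr_mult": hit[0] if hit else np.nan,
                     "ical_mult": hit[1] if hit else np.nan})
    return pd.DataFrame(rows)


def dad_threshold_scan(models, cao_grid=(3.25, 4.0, 5.0, 6.0, 8.0),
                       serca_mult: float = 1.0, rate_hz: float = 2.5,
                       n_beats: int = 60, tail_ms: float = 3000.0,
                       s0=None) -> pd.DataFrame:
    """Minimal extracellular calcium producing spontaneous diastolic events
    after rapid prepacing with beta-adrenergic stimulation."""
    rows = []
    cao_grid = sorted(cao_grid, reverse=True)  # strongest first
    for i, q in enumerate(models):
        qq = q.with_multipliers({"SERCA": serca_mult}) \
            if serca_mult != 1.0 else q
        hit = np.nan
        for cao in cao_grid:
            r = dad_assay(qq, rate_hz=rate_hz, n_beats=n_beats, cao=cao,
                          tail_ms=tail_ms, s0=s0)
            if r["dads"] or r["triggered"]:
                hit = cao
            else:
                break   # weaker loading will not succeed either
        rows.append({"model": i, "capable": np.isfinite(hit),
                     "cao_threshold": hit})
    return pd.DataFrame(rows)


def alternans_capability_scan(models, bcl: float = 260.0,
                              jup_mults=None, n_beats: int = 60,
                              s0=None) -> pd.DataFrame:
    """Does any SERCA multiplier produce alternans at the test cycle length?

    Models failing 1:1 capture at the test cycle length are excluded
    (capture check precedes the scan)."""
    if jup_mults is None:
        jup_mults = np.round(np.arange(0.5, 1.51, 0.1), 1)
    jup_mults = sorted(jup_mults)  # low SERCA first: most alternans-prone
    rows = []
    for i, q in enumerate(models):
        cap = alternans_assay(q, [bcl], n_beats=n_beats, s0=s0)
        if not bool(cap.captured.iloc[0]):
            rows.append({"model": i, "captures": False, "capable": False,
                         "n_hits": 0})
            continue
        hit = False
        n_hits = 0
        for jm in jup_mults:
            df = alternans_assay(q, [bcl], n_beats=n_beats,
                                 serca_mult=float(jm), s0=s0)
            if bool(df.alternans.iloc[0]) and bool(df.captured.iloc[0]):
                hit = True
                n_hits += 1
                break
        rows.append({"model": i, "captures": True, "capable": hit,
                     "n_hits": n_hits})
    return pd.DataFrame(rows)


def restitution_slope_scan(models, s1: float = 1000.0, n_s1: int = 15,
                           s2_list=None, s0=None) -> pd.DataFrame:
    rows = []
    for i, q in enumerate(models):
        r = s1s2_restitution(q, s1=s1, n_s1=n_s1, s2_list=s2_list, s0=s0)
        rows.append({"model": i, "max_slope": r["max_slope"],
                     "apd_ss": r["apd_ss"],
                     "steep": bool(np.isfinite(r["max_slope"])
                                   and r["max_slope"] > 1.0)})
    return pd.DataFrame(rows)
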