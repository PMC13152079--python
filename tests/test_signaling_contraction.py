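"""CaMKII / beta-adrenergic cascade behavior and the contraction model."""

import numpy as np
import pytest

from myocyte import build_parameters, pace
from myocyte.contraction import (contraction_dynamics, isometric_tension,
                                 set_sarcomere_stretch)
from myocyte.signaling import (agonist_from_concentration, bars_dynamics,
                               camkii_dynamics, pka_targets, set_bars)
from myocyte.states import IX


def test_baseline_modifiers_are_unity(male, y_male):
    r = bars_dynamics(y_male, male, agonist=0.0)
    for k, v in r["targets"].items():
        if k.endswith("shift_mV"):
            assert v == pytest.approx(0.0, abs=1e-9)
        else:
            assert v == pytest.approx(1.0, abs=1e-9)


def test_cascade_relaxes_to_baseline_without_agonist(male, y_male):
    """With agonist 0, phosphorylated initial conditions decay toward 0."""
    y = y_male.copy()
    y[IX["a_pka"]] = 0.4
    for k in ("p_ical", "p_iks", "p_plb", "p_ryr", "p_inak", "p_tni"):
        y[IX[k]] = 0.8
    r = bars_dynamics(y, male, agonist=0.0)
    assert r["d_pka"] < 0
    assert all(v < 0 for v in r["d_phospho"].values())


def test_saturating_agonist_drives_phosphorylation_up(male, y_male):
    r = bars_dynamics(y_male, male, agonist=True)
    assert r["d_pka"] > 0


def test_graded_agonist_mapping_monotone():
    vals = [agonist_from_concentration(c) for c in (0.0, 0.01, 0.1, 1.0)]
    assert vals[0] == 0.0
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert vals[-1] > 0.9


def test_camkii_basal_at_diastolic_calcium(male, y_male):
    """With no trapped kinase and calcium clamped at the diastolic level,
    activity reduces to the small calcium-bound fraction and the target
    modifiers stay near 1."""
    y = y_male.copy()
    y[IX["camk_trap"]] = 0.0
    y[IX["ca_dyad"]] = 1.0e-4
    r = camkii_dynamics(y, male)
    assert r["active"] < 0.01
    for k, v in r["targets"].items():
        if k != "INaL_phospho_fraction":
            assert v == pytest.approx(1.0, abs=0.05)


def test_camkii_activity_increases_with_pacing_rate(male, y_male):
    """Steady-state CaMKII activity is higher at 2 Hz than at 0.5 Hz."""
    tr_fast = pace(male, 500.0, 40, y0=y_male, record_from=39)
    tr_slow = pace(male, 2000.0, 10, y0=y_male, record_from=9)
    camk_fast = tr_fast.y[-1, IX["camk_trap"]]
    camk_slow = tr_slow.y[-1, IX["camk_trap"]]
    assert camk_fast > camk_slow


def test_tension_zero_at_diastolic_calcium(male, y_male):
    y = y_male.copy()
    y[IX["xb_s"]] = 0.0
    y[IX["xb_w"]] = 0.0
    assert isometric_tension(y, male) == pytest.approx(0.0, abs=1e-12)
    # converged diastolic tension is a small fraction of systolic
    from myocyte.snapshots import steady_state
    from myocyte import pace
    tr = pace(male, 1000.0, 2, y0=y_male, record_from=1)
    assert isometric_tension(y_male, male) < 0.15 * tr.tension.max()


def test_tension_proportional_to_strong_crossbridges(male, y_male):
    y = y_male.copy()
    y[IX["xb_s"]] = 0.1
    t1 = isometric_tension(y, male)
    y[IX["xb_s"]] = 0.2
    t2 = isometric_tension(y, male)
    assert t2 == pytest.approx(2.0 * t1, rel=1e-12)


def test_longer_sarcomere_gives_larger_tension_and_sensitivity(male, y_male):
    """Length-dependent activation: at identical state, tension rises with
    stretch, and the troponin on-rate rises too (lower Ca50)."""
    y = y_male.copy()
    y[IX["xb_s"]] = 0.05
    p_short = set_sarcomere_stretch(male, 1.0)
    p_long = set_sarcomere_stretch(male, 1.15)
    assert isometric_tension(y, p_long) > isometric_tension(y, p_short)
    y2 = y.copy()
    y2[IX["ca_myo"]] = 4e-4
    d_short = contraction_dynamics(y2, p_short)["derivatives"]["ca_trpn"]
    d_long = contraction_dynamics(y2, p_long)["derivatives"]["ca_trpn"]
    assert d_long > d_short


def test_stretch_validation():
    p = build_parameters("male")
    with pytest.raises(ValueError):
        set_sarcomere_stretch(p, -1.0)
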