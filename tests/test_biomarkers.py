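"""Biomarker extractors and event detectors are exact on constructed
synthetic fixtures."""

import numpy as np
import pytest

from myocyte import biomarkers as bm
from myocyte.io import generate_fixture


def test_square_ap_width_recovered_exactly():
    tr = generate_fixture("square_ap", width=300.0, dt=0.5)
    assert bm.apd(tr, 0, 90.0) == pytest.approx(300.0, abs=1.0)
    assert bm.apd(tr, 0, 50.0) == pytest.approx(300.0, abs=1.0)


@pytest.mark.parametrize("width", [120.0, 250.0, 400.0])
def test_square_ap_width_parametrized(width):
    tr = generate_fixture("square_ap", width=width, dt=0.25)
    assert bm.apd(tr, 0, 90.0) == pytest.approx(width, abs=0.5)


def test_apd_level_ordering_on_real_beat(beat_male):
    a50 = bm.apd(beat_male, 0, 50.0)
    a90 = bm.apd(beat_male, 0, 90.0)
    assert 0 < a50 < a90


def test_triangle_cat_metrics_exact():
    tr = generate_fixture("triangle_cat", ttp=40.0, decay=300.0,
                          dia=1e-4, amp=5e-4, dt=0.5)
    b = tr.beat_slice(0)
    dia, amp, ttp, d50, d90 = bm.cat_metrics(b.t, b.state("ca_myo"), 1.0)
    assert dia == pytest.approx(1e-4)
    assert amp == pytest.approx(5e-4, rel=0.02)
    assert ttp == pytest.approx(40.0, abs=1.0)
    assert d50 == pytest.approx(40.0 + 150.0, abs=2.0)
    assert d90 == pytest.approx(40.0 + 270.0, abs=2.0)


def test_triangle_tension_biomarkers_exact():
    tr = generate_fixture("triangle_tension", ttp=150.0, decay=400.0,
                          peak=40.0, dt=0.5)
    r = bm.tension_biomarkers(tr, 0)
    assert r["tension_peak"] == pytest.approx(40.0, rel=0.01)
    assert r["tension_ttp"] == pytest.approx(150.0, abs=1.0)
    assert r["tension_rt95"] == pytest.approx(0.95 * 400.0, abs=2.0)


def test_alternating_apd_magnitude_exact():
    tr = generate_fixture("alternating_apd", widths=(280.0, 240.0),
                          n_beats=10, dt=0.5)
    apds = [bm.apd(tr, b) for b in range(10)]
    mag, _ = bm.alternans_magnitude(np.array(apds), 10)
    assert mag == pytest.approx(40.0, abs=1.5)


def test_dad_fixture_detected_once_no_triggered_ap():
    tr = generate_fixture("dad_like_diastole", bumps=[(500.0, 3.0)])
    dads, trig = bm.detect_dads(tr.t, tr.v)
    assert len(dads) == 1
    assert trig == []
    assert dads[0][1] == pytest.approx(3.0, abs=0.2)


def test_dad_below_threshold_not_counted():
    tr = generate_fixture("dad_like_diastole", bumps=[(500.0, 0.5)])
    dads, trig = bm.detect_dads(tr.t, tr.v)
    assert dads == [] and trig == []


def test_triggered_ap_not_double_counted_as_dad():
    tr = generate_fixture("dad_like_diastole",
                          bumps=[(500.0, 3.0), (1200.0, 60.0)])
    dads, trig = bm.detect_dads(tr.t, tr.v)
    assert len(trig) == 1
    assert len(dads) == 1          # only the subthreshold bump


def test_no_eads_on_clean_beat(beat_male):
    b = beat_male.beat_slice(0)
    assert bm.detect_eads(b.t, b.v) == []


def test_clearance_fractions_pure_uptake_limit(beat_male):
    """With NCX and pCa fluxes zeroed in the trace, the split is (1, 0, 0)."""
    from myocyte._kernel import OX
    tr = beat_male
    tr2 = type(tr)(tr.t.copy(), tr.y.copy(), tr.out.copy(),
                   tr.stim_times.copy())
    tr2.out[:, OX["jncx_ca"]] = 0.0
    tr2.out[:, OX["jpca_ca"]] = 0.0
    cf = bm.clearance_fractions(tr2, 0)
    assert cf["SERCA"] == pytest.approx(1.0)
    assert cf["NCX"] == 0.0
    assert cf["pCa"] == 0.0
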