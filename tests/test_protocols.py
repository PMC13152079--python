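"""Protocol engine plumbing (cheap checks; the physiology-level assays are
exercised in the acceptance suite)."""

import numpy as np
import pytest

from myocyte.protocols import (FIG1E_DRUGS, Protocol, run_protocol,
                               s1s2_restitution, steady_pacing)


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol(kind="steady_pacing", bcl_ms=-10.0, rate_hz=None)
    with pytest.raises(ValueError):
        Protocol(drug_block={"IKr": 1.4})
    with pytest.raises(ValueError):
        Protocol(kind="s1s2_restitution", s2_list=[400.0, 300.0])


def test_block_fractions_become_remaining_multipliers():
    proto = Protocol(drug_block={"IKr": 0.70, "ICaL": 0.20})
    assert proto.multipliers == {"IKr": pytest.approx(0.30),
                                 "ICaL": pytest.approx(0.80)}


def test_mexiletine_is_three_target_block():
    blk = FIG1E_DRUGS["mexiletine"]
    rem = {k: 1.0 - v for k, v in blk.items()}
    assert rem == {"INaL": pytest.approx(0.54), "IKr": pytest.approx(0.09),
                   "ICaL": pytest.approx(0.20)}


def test_steady_pacing_protocol_runs_and_records(male, y_male):
    proto = Protocol(kind="steady_pacing", rate_hz=1.0, n_beats=2,
                     record_last=1)
    tr = run_protocol(male, proto, s0=y_male)
    assert len(tr.stim_times) == 1
    assert tr.t[-1] - tr.t[0] >= 990.0


def test_unknown_protocol_kind_rejected(male):
    with pytest.raises(ValueError):
        run_protocol(male, Protocol(kind="tissue_sim"))


def test_s2_equal_to_s1_recovers_steady_apd(male, y_male):
    """The S1-S2 limit case: an S2 interval equal to S1 gives the
    steady-state APD."""
    r = s1s2_restitution(male, s1=1000.0, n_s1=3,
                         s2_list=[1000.0], s0=y_male)
    apd_s2 = r["curve"].apd90.iloc[0]
    assert apd_s2 == pytest.approx(r["apd_ss"], abs=2.0)


def test_assays_are_pure_functions_of_inputs(male, y_male):
    r1 = s1s2_restitution(male, s1=1000.0, n_s1=2,
                          s2_list=[400.0, 600.0], s0=y_male)
    r2 = s1s2_restitution(male, s1=1000.0, n_s1=2,
                          s2_list=[400.0, 600.0], s0=y_male)
    assert np.array_equal(r1["curve"].apd90.to_numpy(),
                          r2["curve"].apd90.to_numpy())


def test_drug_panel_directions(male, y_male):
    """Channel-block signatures: IKr block prolongs APD with reverse rate
    dependence (more at slow rate); ICaL block shortens APD."""
    from myocyte.protocols import drug_panel
    df = drug_panel(male,
                    drugs={"E-4031": {"IKr": 0.70},
                           "nisoldipine": {"ICaL": 0.90}},
                    rates=(0.5, 2.0), n_beats=40, s0=y_male)
    e = df[df.drug == "E-4031"].set_index("rate_hz").delta_apd90
    n = df[df.drug == "nisoldipine"].set_index("rate_hz").delta_apd90
    assert (e > 0).all()                   # IKr block prolongs
    assert e.loc[0.5] > e.loc[2.0]         # reverse rate dependence
    assert (n < 0).all()                   # ICaL block shortens
    base = df[df.drug == "baseline"]
    assert (base.delta_apd90 == 0).all()


def test_ead_threshold_scan_orders_apd(male, y_male):
    """Stronger IKr block gives longer APD; the baseline point shows no
    afterdepolarizations."""
    from myocyte.protocols import ead_threshold_scan
    df = ead_threshold_scan(male, ikr_multipliers=[1.0, 0.4], n_beats=4,
                            s0=y_male)
    assert df[df.ikr_mult == 1.0].ead_count.iloc[0] == 0
    assert df[df.ikr_mult == 0.4].apd90.iloc[0] > \
        df[df.ikr_mult == 1.0].apd90.iloc[0]


def test_apd_vs_slope_study_reproducible(male, y_male):
    """Identical parameter sets map to identical (APD, slope) points."""
    from myocyte.protocols import apd_vs_slope_study
    s2 = [300.0, 330.0, 360.0, 420.0, 600.0, 1000.0]
    df = apd_vs_slope_study([male, male], n_s1=6, s0=y_male, s2_list=s2)
    assert df.apd_ss.iloc[0] == df.apd_ss.iloc[1]
    assert df.max_slope.iloc[0] == df.max_slope.iloc[1]
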