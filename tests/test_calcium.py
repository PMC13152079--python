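"""Calcium handling: release, uptake, buffering, diffusion."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from myocyte._kernel import OX, rhs_py
from myocyte.calcium import (buffer_equilibrium, compute_buffering_and_diffusion,
                             compute_Jrel, compute_Jup_Jleak,
                             ryr_transition_rates)
from myocyte.states import IX


def test_jrel_zero_with_empty_store(male, y_male):
    y = y_male.copy()
    y[IX["ca_sr"]] = y[IX["ca_dyad"]]     # no gradient -> no release flux
    r = compute_Jrel(y, male)
    assert r["Jrel"] == pytest.approx(0.0, abs=1e-15)


def test_jup_zero_with_serca_disabled(male, y_male):
    q = male.with_multipliers({"SERCA": 0.0})
    assert compute_Jup_Jleak(y_male, q)["Jup"] == 0.0


def test_jup_saturates_in_cytosolic_calcium(male, y_male):
    vals = []
    for ca in [1e-4, 3e-4, 1e-3, 3e-3, 1e-2]:
        y = y_male.copy()
        y[IX["ca_myo"]] = ca
        vals.append(compute_Jup_Jleak(y, male)["Jup"])
    assert all(b > a for a, b in zip(vals, vals[1:]))
    gain_low = (vals[1] - vals[0]) / 2e-4
    gain_high = (vals[4] - vals[3]) / 7e-3
    assert gain_high < 0.1 * gain_low     # saturation


def test_diffusion_zero_at_equal_concentrations(male, y_male):
    y = y_male.copy()
    c = 2e-4
    for n in ("ca_myo", "ca_sl", "ca_dyad"):
        y[IX[n]] = c
    r = compute_buffering_and_diffusion(y, male)
    assert r["Jdiff_dyad_sl"] == pytest.approx(0.0, abs=1e-18)
    assert r["Jdiff_sl_myo"] == pytest.approx(0.0, abs=1e-18)


def test_buffer_occupancy_matches_algebraic_equilibrium(male, y_male):
    """Integrating the calmodulin-buffer ODE at clamped Ca converges to the
    closed-form bound fraction."""
    ca = 4e-4
    kd = male["koff_cam"] / male["kon_cam"]
    expected = buffer_equilibrium(ca, male["bmax_cam"], male["kon_cam"],
                                  male["koff_cam"])

    def ode(t, b):
        return male["kon_cam"] * ca * (male["bmax_cam"] - b) \
            - male["koff_cam"] * b

    sol = solve_ivp(ode, (0.0, 500.0), [0.0], rtol=1e-10, atol=1e-14)
    assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)
    assert expected == pytest.approx(male["bmax_cam"] * ca / (kd + ca))


def test_ryr_isolated_subsystem_matches_reference_integration(male, y_male):
    """Clamped dyadic-Ca step: the RyR occupancies inside the full RHS follow
    the same trajectory as an independent stiff integration of the isolated
    four-state scheme."""
    cad, casr = 0.05, y_male[IX["ca_sr"]]
    # signaling state feeding the RyR sensitization at the test state
    y_sig = y_male.copy()
    y_sig[IX["ca_dyad"]] = cad
    from myocyte.signaling import camkii_dynamics
    camk = camkii_dynamics(y_sig, male)["active_fraction"]
    rates = ryr_transition_rates(cad, casr, male,
                                 pka=y_male[IX["p_ryr"]], camk=camk)
    ko, kom = rates["k_open"], rates["k_close"]
    ki, kim = rates["k_inact"], rates["k_recover"]

    def iso(t, s):
        r, o, i = s
        ri = 1.0 - r - o - i
        dr = (kim * ri - ki * r) - (ko * r - kom * o)
        do = (ko * r - kom * o) - (ki * o - kim * i)
        di = (ki * o - kim * i) - (kom * i - ko * ri)
        return [dr, do, di]

    s0 = [y_male[IX["ryr_r"]], y_male[IX["ryr_o"]], y_male[IX["ryr_i"]]]
    ref = solve_ivp(iso, (0.0, 50.0), s0, method="LSODA",
                    rtol=1e-10, atol=1e-12, t_eval=[50.0])

    # step the full RHS with calcium clamped by resetting concentrations
    y = y_male.copy()
    y[IX["ca_dyad"]] = cad
    dt = 1e-3
    s = np.array(s0)
    for _ in range(int(50.0 / dt)):
        y[IX["ryr_r"]], y[IX["ryr_o"]], y[IX["ryr_i"]] = s
        dy, _ = rhs_py(0.0, y, male.vec)
        s = s + dt * np.array([dy[IX["ryr_r"]], dy[IX["ryr_o"]],
                               dy[IX["ryr_i"]]])
    assert np.allclose(s, ref.y[:, -1], atol=2e-4)


def test_sr_load_release_relationship_positive_and_steep(male, y_male):
    """More SR calcium yields disproportionately more release at a fixed
    trigger (open fraction and driving force both grow with load)."""
    rel = []
    for casr in [0.8, 1.2, 1.6, 2.0]:
        y = y_male.copy()
        y[IX["ca_sr"]] = casr
        y[IX["ca_dyad"]] = 0.02
        y[IX["ryr_o"]] = 0.02
        y[IX["ryr_r"]] = 0.8
        r = compute_Jrel(y, male)
        rel.append(r["Jrel"])
        # opening rate itself accelerates with load
    assert all(b > a for a, b in zip(rel, rel[1:]))

    k_lo = ryr_transition_rates(0.02, 0.8, male)["k_open"]
    k_hi = ryr_transition_rates(0.02, 2.0, male)["k_open"]
    assert k_hi > 2.0 * k_lo


def test_camkii_and_pka_hooks_modulate_uptake(male, y_male):
    y = y_male.copy()
    y[IX["ca_myo"]] = 3e-4
    base = compute_Jup_Jleak(y, male)["Jup"]
    y2 = y.copy()
    y2[IX["p_plb"]] = 1.0
    assert compute_Jup_Jleak(y2, male)["Jup"] > base
    y3 = y.copy()
    y3[IX["camk_trap"]] = 0.5
    assert compute_Jup_Jleak(y3, male)["Jup"] > base
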