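"""Current formulations: reversal potentials, thermodynamic nulls,
monotonicity sweeps and the pore-block (multiplier) drug model."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from myocyte import build_parameters
from myocyte._kernel import OX, rhs_py
from myocyte.currents import (compute_currents, compute_INaCa, compute_INaK,
                              reversal_potentials)
from myocyte.parameters import FARADAY, R_GAS, TEMP
from myocyte.states import IX

FRT = FARADAY / (R_GAS * TEMP)


def test_reversal_potential_zero_at_equal_concentrations(male, y_male):
    y = y_male.copy()
    y[IX["k_i"]] = male["ko"]
    assert reversal_potentials(y, male)["K"] == pytest.approx(0.0, abs=1e-12)


def test_potassium_nernst_value(male, y_male):
    """[K]o 5.4 / [K]i 144 at 37 C gives E_K near -87.8 mV (direct Nernst)."""
    y = y_male.copy()
    y[IX["k_i"]] = 144.0
    ek = reversal_potentials(y, male)["K"]
    assert ek == pytest.approx(math.log(5.4 / 144.0) / FRT, rel=1e-12)
    assert ek == pytest.approx(-87.8, abs=0.3)


def test_reversal_monotone_in_concentration_ratio(male, y_male):
    eks = []
    for ki in [100.0, 120.0, 144.0, 160.0]:
        y = y_male.copy()
        y[IX["k_i"]] = ki
        eks.append(reversal_potentials(y, male)["K"])
    assert all(a > b for a, b in zip(eks, eks[1:]))
    # sodium reversal well above potassium reversal physiologically
    rp = reversal_potentials(y_male, male)
    assert rp["Na"] > rp["K"]


def test_ik1_zero_at_potassium_reversal(male, y_male):
    y = y_male.copy()
    ek = reversal_potentials(y, male)["K"]
    y[IX["v"]] = ek
    cs = compute_currents(y, male)
    assert cs["ik1"] == pytest.approx(0.0, abs=1e-12)
    assert cs["ito"] == pytest.approx(0.0, abs=1e-12)
    assert cs["ikr"] == pytest.approx(0.0, abs=1e-12)


def test_inak_vanishes_without_sodium(male, y_male):
    y = y_male.copy()
    y[IX["na_sl"]] = 1e-6
    y[IX["na_myo"]] = 1e-6
    assert compute_INaK(y, male) == pytest.approx(0.0, abs=1e-6)


def test_inak_increases_with_intracellular_sodium(male, y_male):
    vals = []
    for na in np.linspace(4.0, 14.0, 8):
        y = y_male.copy()
        y[IX["na_sl"]] = na
        y[IX["na_myo"]] = na
        vals.append(compute_INaK(y, male))
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_ncx_zero_at_thermodynamic_equilibrium(male, y_male):
    """3Na:1Ca stoichiometry: the exchanger reverses at
    V = 3 E_Na - 2 E_Ca."""
    y = y_male.copy()
    ca = 2e-4
    y[IX["ca_sl"]] = ca
    y[IX["ca_dyad"]] = ca
    e_na = math.log(male["nao"] / y[IX["na_sl"]]) / FRT
    e_ca = math.log(male["cao"] / ca) / (2.0 * FRT)
    y[IX["v"]] = 3.0 * e_na - 2.0 * e_ca
    r = compute_INaCa(y, male)
    assert r["INaCa"] == pytest.approx(0.0, abs=1e-10)


def test_ncx_forward_mode_decreases_with_sodium_loading(male, y_male):
    """Raising intracellular Na at fixed V and Ca shifts the exchanger away
    from forward (Ca-extruding, inward-current) mode."""
    vals = []
    for na in np.linspace(6.0, 16.0, 6):
        y = y_male.copy()
        y[IX["v"]] = -80.0
        y[IX["ca_sl"]] = 3e-4
        y[IX["ca_dyad"]] = 3e-4
        y[IX["na_sl"]] = na
        y[IX["na_myo"]] = na
        vals.append(compute_INaCa(y, male)["INaCa"])
    # forward mode gives negative current; loading Na makes it less negative
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_ical_zero_at_zero_open_probability(male, y_male):
    y = y_male.copy()
    y[IX["d"]] = 0.0
    cs = compute_currents(y, male)
    assert cs["ical"] == 0.0
    assert cs["icana"] == 0.0
    assert cs["icak"] == 0.0


def test_drug_block_linearity(male, y_male):
    """Pore-block model: scaling a conductance by f scales that current by f
    at identical state."""
    y = y_male.copy()
    y[IX["v"]] = -20.0
    base = compute_currents(y, male)
    for target, key in [("IKr", "ikr"), ("ICaL", "ical"), ("INaL", "inal"),
                        ("IK1", "ik1")]:
        q = male.with_multipliers({target: 0.37})
        cs = compute_currents(y, q)
        assert cs[key] == pytest.approx(0.37 * base[key], rel=1e-12)


@pytest.mark.parametrize("gate,clamp_v", [
    ("m", -40.0), ("hf", -80.0), ("j", -70.0), ("d", 0.0), ("ff", -10.0),
    ("xrf", -20.0), ("xs1", 0.0), ("a", 10.0), ("if_", -30.0), ("ml", -40.0),
    ("hl", -80.0), ("jca", -50.0),
])
def test_gate_equilibrium_matches_root_finding(male, y_male, gate, clamp_v):
    """At clamped V (and Ca), the equilibrium of each gating ODE found by an
    independent root solve matches the integrator's fixed point to 1e-8."""
    y = y_male.copy()
    y[IX["v"]] = clamp_v

    def dgate(x):
        y2 = y.copy()
        y2[IX[gate]] = x
        dy, _ = rhs_py(0.0, y2, male.vec)
        return dy[IX[gate]]

    root = brentq(dgate, -0.001, 1.001, xtol=1e-14)
    # independent relaxation of the isolated scalar ODE from both ends
    from scipy.integrate import solve_ivp
    for x0 in (0.0, 1.0):
        sol = solve_ivp(lambda t, x: [dgate(x[0])], (0.0, 30000.0), [x0],
                        method="LSODA", rtol=1e-12, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(root, abs=1e-8)


def test_fca_equilibrium_tracks_dyadic_calcium(male, y_male):
    """Brute-force equilibrium of the CDI gate at clamped Ca matches the
    closed-form steady state."""
    for cad in [1e-4, 5e-3, 2e-2, 0.1]:
        y = y_male.copy()
        y[IX["ca_dyad"]] = cad

        def dfca(x):
            y2 = y.copy()
            y2[IX["fca"]] = x
            dy, _ = rhs_py(0.0, y2, male.vec)
            return dy[IX["fca"]]

        root = brentq(dfca, -0.001, 1.001, xtol=1e-12)
        expected = 1.0 / (1.0 + (cad / male["km_cdi"]) ** 2)
        assert root == pytest.approx(expected, abs=1e-10)
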