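"""Ion-bookkeeping contracts: the RHS conserves each species exactly, and
time-integrated sarcolemmal fluxes match content changes."""

import numpy as np
import pytest

from myocyte import SolverSettings, pace
from myocyte._kernel import OX, rhs_py
from myocyte.parameters import ACAP, FARADAY, V_DYAD, V_K, V_MYO, V_SL, V_SR
from myocyte.states import IX


def total_contents(y, p):
    """Total Na, K, Ca content (free + buffered, all compartments) in
    cell-volume-normalized mmol units (uL * mM)."""
    na = y[IX["na_myo"]] * V_MYO + y[IX["na_sl"]] * V_SL
    k = y[IX["k_i"]] * V_K
    ca = (y[IX["ca_myo"]] * V_MYO + y[IX["ca_sl"]] * V_SL
          + y[IX["ca_dyad"]] * V_DYAD + y[IX["ca_sr"]] * V_SR
          + y[IX["b_cam"]] * V_MYO
          + y[IX["ca_trpn"]] * p["trpn_tot"] * V_MYO
          + (y[IX["b_sll_sl"]] + y[IX["b_slh_sl"]]) * V_SL
          + (y[IX["b_sll_d"]] + y[IX["b_slh_d"]]) * V_DYAD
          + y[IX["b_csqn"]] * V_SR)
    return na, k, ca


def content_derivative(dy, p):
    """d/dt of total Na, K, Ca content as a linear combination of state
    derivatives (exact; no finite differences)."""
    na = dy[IX["na_myo"]] * V_MYO + dy[IX["na_sl"]] * V_SL
    k = dy[IX["k_i"]] * V_K
    ca = (dy[IX["ca_myo"]] * V_MYO + dy[IX["ca_sl"]] * V_SL
          + dy[IX["ca_dyad"]] * V_DYAD + dy[IX["ca_sr"]] * V_SR
          + dy[IX["b_cam"]] * V_MYO
          + dy[IX["ca_trpn"]] * p["trpn_tot"] * V_MYO
          + (dy[IX["b_sll_sl"]] + dy[IX["b_slh_sl"]]) * V_SL
          + (dy[IX["b_sll_d"]] + dy[IX["b_slh_d"]]) * V_DYAD
          + dy[IX["b_csqn"]] * V_SR)
    return np.array([na, k, ca])


def membrane_fluxes(out):
    """Independent bookkeeping oracle: signed sums of the transmembrane
    currents per species (uA/uF), converted to content derivatives."""
    g = lambda n: out[OX[n]]
    i_na = (g("ina") + g("inal") + g("inab") + g("icana")
            + 3.0 * g("inaca") + 3.0 * g("inak"))
    i_k = (g("ito") + g("ikr") + g("iks") + g("ik1") + g("ikb") + g("icak")
           - 2.0 * g("inak") + g("istim"))
    i_ca = (g("ical") + g("icab") + g("ipca") - 2.0 * g("inaca"))
    c = ACAP / FARADAY
    return -i_na * c, -i_k * c, -i_ca * c / 2.0


@pytest.mark.parametrize("species", ["na", "k", "ca"])
def test_rhs_conserves_each_species_exactly(beat_male, male, species):
    """d(total content)/dt from the state derivatives equals the signed sum
    of transmembrane currents, to near machine precision."""
    idx = {"na": 0, "k": 1, "ca": 2}[species]
    for i in [0, 5, 40, 200, 900, 1500]:
        y = beat_male.y[i]
        t = beat_male.t[i]
        stim = beat_male.out[i, OX["istim"]]
        dy, out = rhs_py(t, y, male.vec, stim)
        # total-content derivative: the content is linear in the states, so
        # it is an exact linear combination of the state derivatives
        dcontent = content_derivative(dy, male)
        expected = membrane_fluxes(out)[idx]
        scale = max(abs(expected), 1e-9)
        assert dcontent[idx] == pytest.approx(expected, abs=1e-9 + 1e-7 * scale)


def test_integrated_calcium_conservation_over_a_beat(male, y_male):
    """Total calcium change over one beat equals the integrated sarcolemmal
    calcium flux (trapezoid on dense 0.05 ms output)."""
    tr = pace(male, 1000.0, 1, y0=y_male,
              settings=SolverSettings(dt_sample=0.05))
    flux = -(tr.out[:, OX["ical"]] + tr.out[:, OX["icab"]]
             + tr.out[:, OX["ipca"]] - 2.0 * tr.out[:, OX["inaca"]]) \
        * ACAP / (2.0 * FARADAY)
    integral = np.trapezoid(flux, tr.t)
    ca0 = total_contents(tr.y[0], male)[2]
    ca1 = total_contents(tr.y[-1], male)[2]
    assert (ca1 - ca0) == pytest.approx(integral, rel=None,
                                        abs=1e-6 * ca0)


def test_gate_perturbation_sparsity(male, y_male):
    """Perturbing a single gating variable changes only that gate's own ODE
    and the non-gating (voltage/concentration) equations."""
    from myocyte.states import GATE_NAMES
    y = y_male.copy()
    dy0, _ = rhs_py(0.0, y, male.vec)
    for gate in ["m", "xs1", "jca", "hl"]:
        y2 = y.copy()
        y2[IX[gate]] = min(1.0, y2[IX[gate]] + 0.1) if y2[IX[gate]] < 0.9 \
            else y2[IX[gate]] - 0.1
        dy1, _ = rhs_py(0.0, y2, male.vec)
        changed = {i for i in range(len(dy0))
                   if abs(dy1[i] - dy0[i]) > 1e-12 * max(1.0, abs(dy0[i]))}
        other_gates = {IX[g] for g in GATE_NAMES if g != gate}
        assert not (changed & other_gates), gate
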