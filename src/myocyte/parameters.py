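"""Parameter sets for the ventricular cardiomyocyte model.

All parameters live in a flat float64 vector so that the compiled right-hand
side can index them positionally; this module owns the name <-> index mapping,
the male (baseline endocardial) defaults, the female multiplier overlay, and
the named multiplier targets used for drug block, signaling studies and
population sampling.

Units convention: mV, ms, mM, uA/uF; volumes in uL; permeabilities follow the
GHK bookkeeping of the ORd family (current in uA/uF).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

# physical constants
R_GAS = 8314.0       # J / (kmol K)
FARADAY = 96485.0    # C / mol
TEMP = 310.0         # K

# cell geometry (cylinder, ORd-style): length 100 um, radius 11 um
_VCELL = 3.801e-5    # uL
ACAP = 1.534e-4      # cm^2 (uF at 1 uF/cm^2)
V_MYO = 0.65 * _VCELL
V_SL = 0.02 * _VCELL
V_DYAD = 2.0e-3 * _VCELL
V_SR = 0.04 * _VCELL
V_K = V_MYO + V_SL + V_DYAD   # potassium treated as a single well-mixed pool

# ---------------------------------------------------------------------------
# ordered registry: (name, baseline male endocardial value)
# ---------------------------------------------------------------------------
_REGISTRY: list[tuple[str, float]] = [
    # extracellular milieu
    ("nao", 140.0), ("cao", 1.8), ("ko", 5.4), ("clo", 150.0), ("cli", 24.0),
    # maximal conductances / permeabilities (uA/uF scale)
    ("gna", 75.0),
    ("gnal", 0.0125),
    ("gto", 0.02),
    ("pca", 0.00107898),
    ("gkr", 0.217854),
    ("gks", 0.00465114),
    ("gk1", 0.62),
    ("gncx", 4.06),
    ("pnak", 2.6),
    ("gpca", 0.026),
    ("gnab", 1.1e-4),
    ("pcab", 1.03791e-07),
    ("gkb", 0.0030),
    ("gclca", 0.0055),
    ("kdclca", 0.1),
    ("gclb", 0.0011),
    # ICaL details
    ("rel_pcana", 1.25e-3), ("rel_pcak", 3.574e-4),
    ("frac_ical_dyad", 0.85),
    ("km_cdi", 0.012906),        # mM dyadic Ca at half CDI
    ("tau_fca_min", 3.0), ("tau_fca_rec", 128.379),
    ("vhalf_jca", -40.0), ("slope_jca", 6.0), ("tau_jca", 153.854),
    ("jca_floor", 0.0),
    ("w_cdi_escape", 0.0),
    # NCX
    ("kmcai", 3.59e-3), ("kmcao", 1.3), ("kmnai", 12.29), ("kmnao", 87.5),
    ("ksat", 0.27), ("eta_ncx", 0.35), ("kdact", 8.5e-4),
    ("frac_ncx_dyad", 0.18),
    # NaK pump
    ("kmnainak", 11.0), ("kmko", 1.5),
    # RyR (calcium-sensitive population, Shannon-style with refractory state)
    ("ko_ryr", 22.0214), ("kom", 0.06), ("ki_ryr", 4.0), ("kim", 0.0015),
    ("km_refrac", 1.0),
    ("casr_so_thr", 2.1), ("so_scale", 0.04),
    ("maxsr", 15.0), ("minsr", 1.0), ("ec50sr", 0.45), ("hsr", 2.5),
    ("grel", 0.556481),           # /ms, SR-volume basis
    # ICaL-coupled RyR subset
    ("gicl", 0.124041), ("trig_k", 1.2), ("tau_y_on", 2.0),
    ("trig_k2", 0.0008), ("tau_y2_inact", 30.0), ("tau_y2_rec", 120.0),
    # SERCA / leak
    ("vup", 0.00035749), ("kmf", 2.4e-4), ("kmr", 2.58122), ("hill_up", 1.25),
    ("gleak", 1.1e-05),
    # inter-compartment diffusion time constants (ms)
    ("tau_ds", 0.03), ("tau_sm", 0.917689), ("tau_na", 2.0),
    # buffers (local mM; kon /mM/ms; koff /ms)
    ("bmax_cam", 0.05), ("kon_cam", 34.0), ("koff_cam", 0.238),
    ("bmax_sll_sl", 1.2), ("kon_sll", 100.0), ("koff_sll", 1.3),
    ("bmax_slh_sl", 0.3), ("kon_slh", 100.0), ("koff_slh", 0.03),
    ("bmax_sll_d", 4.0), ("bmax_slh_d", 1.2),
    ("bmax_csqn", 2.4), ("kon_csqn", 10.0), ("koff_csqn", 6.3),
    # CaMKII
    ("camko", 0.05), ("kmcam", 0.0015), ("acamk", 0.05), ("bcamk", 0.00068),
    ("kmcamk", 0.15),
    ("c_camk_ical", 0.10), ("c_camk_jup", 1.20), ("c_camk_ryr", 0.30),
    # beta-adrenergic couplings (effect size at full phosphorylation)
    ("c_pka_ical", 0.90), ("c_pka_dshift", 8.0),
    ("c_pka_iks", 8.5),
    ("c_pka_plb", 0.6), ("c_pka_vup", 0.27),
    ("c_pka_ryr", 0.2),
    ("c_pka_inak", 0.35),
    ("c_pka_ca50", 0.4), ("c_pka_ktrpn", 1.0), ("c_pka_xb", 3.3),
    ("tau_camp", 6000.0), ("tau_phos", 15000.0),
    # contraction (Land-style)
    ("ca50", 5.8e-4), ("ntrpn", 1.8), ("ktrpn", 0.03), ("trpn_tot", 0.07),
    ("ntm", 1.6), ("ktmb", 0.012), ("ktmu", 0.013),
    ("kuw", 0.012), ("kws", 0.004), ("rw", 0.5), ("rs", 0.25),
    ("tref", 105.0), ("beta0", 2.3), ("beta1", -2.4), ("lam", 1.1),
    # stimulus
    ("stim_amp", -40.0), ("stim_dur", 1.0),
    # beta-adrenergic agonist drive (0 = off, 1 = saturating)
    ("agonist", 0.0),
]

P_NAMES: list[str] = [n for n, _ in _REGISTRY]
P_INDEX: dict[str, int] = {n: i for i, n in enumerate(P_NAMES)}
_BASE_MALE = np.array([v for _, v in _REGISTRY], dtype=np.float64)

# named multiplier targets (drug block, sex overlay, population sampling)
MULTIPLIER_TARGETS: dict[str, str] = {
    "INa": "gna", "INaL": "gnal", "Ito": "gto", "ICaL": "pca",
    "IKr": "gkr", "IKs": "gks", "IK1": "gk1", "INaCa": "gncx",
    "INaK": "pnak", "IpCa": "gpca", "INab": "gnab", "ICab": "pcab",
    "IKb": "gkb", "IClCa": "gclca", "IClb": "gclb",
    "Jup": "vup", "SERCA": "vup", "Jrel": "grel", "Jleak": "gleak",
    "RyR": "ko_ryr", "ICaL_coupled_rel": "gicl",
    "Cao": "cao", "Ko": "ko", "Nao": "nao",
}

# Female overlay: composed from reported human/animal sex differences in
# repolarizing currents and calcium handling (lower IKr/IKs/Ito/IK1, slightly
# reduced SERCA, higher NCX).  Applied multiplicatively to the male set.
FEMALE_OVERLAY: dict[str, float] = {
    "IKr": 0.78, "IKs": 0.88, "Ito": 0.64, "IK1": 0.92,
    "SERCA": 0.97, "INaCa": 1.03,
}

# population-of-models variation set: "key ionic currents and fluxes"
POPULATION_TARGETS: list[str] = [
    "INa", "INaL", "Ito", "ICaL", "IKr", "IKs", "IK1", "INaCa", "INaK",
    "Jup", "Jrel",
]


@dataclass
class Parameters:
    """A complete, validated parameter set.

    ``vec`` is the flat vector consumed by the compiled RHS. ``sex`` and
    ``multipliers`` record provenance so a set can be re-built or serialized.
    """

    vec: np.ndarray
    sex: str = "male"
    multipliers: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.vec[P_INDEX[name]])

    def with_multipliers(self, multipliers: dict[str, float]) -> "Parameters":
        """Return a copy with additional named multipliers applied."""
        merged = dict(self.multipliers)
        p = Parameters(self.vec.copy(), sex=self.sex, multipliers=merged)
        _apply_multipliers(p.vec, multipliers)
        for k, v in multipliers.items():
            merged[k] = merged.get(k, 1.0) * v
        return p

    def copy(self) -> "Parameters":
        return Parameters(self.vec.copy(), self.sex, copy.deepcopy(self.multipliers))

    def set(self, name: str, value: float) -> None:
        self.vec[P_INDEX[name]] = value

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "multipliers": self.multipliers,
            "values": {n: float(self.vec[i]) for i, n in enumerate(P_NAMES)},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_dict(d: dict) -> "Parameters":
        vec = _BASE_MALE.copy()
        for n, v in d.get("values", {}).items():
            vec[P_INDEX[n]] = v
        return Parameters(vec, d.get("sex", "male"), dict(d.get("multipliers", {})))

    @staticmethod
    def from_json(path) -> "Parameters":
        with open(path) as fh:
            return Parameters.from_dict(json.load(fh))


def _apply_multipliers(vec: np.ndarray, multipliers: dict[str, float]) -> None:
    for name, factor in multipliers.items():
        if name not in MULTIPLIER_TARGETS:
            raise ValueError(f"unknown multiplier target: {name!r}")
        if factor < 0:
            raise ValueError(f"multiplier for {name!r} must be >= 0, got {factor}")
        vec[P_INDEX[MULTIPLIER_TARGETS[name]]] *= factor


def build_parameters(preset: str = "male",
                     multipliers: dict[str, float] | None = None) -> Parameters:
    """Build a validated parameter set.

    Parameters
    ----------
    preset : {"male", "female"}
        The female preset is a multiplier overlay on the male set (single
        source of truth); it differs only in documented sex-specific scalings.
    multipliers : mapping of target name -> factor
        Conductance/permeability multipliers (pore-block drug model,
        population sampling, perturbation studies). Unknown names raise.
    """
    if preset not in ("male", "female"):
        raise ValueError(f"unknown preset: {preset!r}")
    vec = _BASE_MALE.copy()
    if preset == "female":
        _apply_multipliers(vec, FEMALE_OVERLAY)
    mult = dict(multipliers or {})
    _apply_multipliers(vec, mult)
    p = Parameters(vec, sex=preset, multipliers=mult)
    _validate(p)
    return p


def _validate(p: Parameters) -> None:
    for n in ("nao", "cao", "ko"):
        if p[n] <= 0:
            raise ValueError(f"extracellular concentration {n} must be > 0")
    if not np.all(np.isfinite(p.vec)):
        bad = [P_NAMES[i] for i in np.flatnonzero(~np.isfinite(p.vec))]
        raise ValueError(f"non-finite parameter(s): {bad}")
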