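"""Compiled right-hand side of the cardiomyocyte model.

One kernel computes every current, flux, signaling and crossbridge rate and
fills (a) the state-derivative vector and (b) a vector of derived outputs
(currents in uA/uF, fluxes in mM/ms on the bulk-myoplasm volume basis, active
tension in kPa). Python-facing wrappers live in `currents`, `calcium`,
`signaling` and `contraction`.

The kernel is written for numba's nopython mode; if numba is unavailable it
runs as plain (slow) Python.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import (ACAP, FARADAY, R_GAS, TEMP, P_INDEX,
                         V_DYAD, V_K, V_MYO, V_SL, V_SR)
from .states import IX, N_STATES

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

FRT = FARADAY / (R_GAS * TEMP)

# --- derived-output registry ------------------------------------------------
OUT_NAMES = [
    "ina", "inal", "ito", "ical", "ical_d", "ical_sl", "icana", "icak",
    "ikr", "iks", "ik1", "inaca", "inaca_d", "inaca_sl", "inak", "ipca",
    "inab", "icab", "ikb", "iclca", "iclb", "istim",
    "jrel", "jrel_ca", "jrel_icl", "jup", "jleak",
    "jncx_ca", "jpca_ca", "jcal_ca", "jcab_ca",
    "tension", "camk_active",
    "e_na", "e_k", "e_ks", "e_cl",
]
N_OUT = len(OUT_NAMES)
OX = {n: i for i, n in enumerate(OUT_NAMES)}

# unpack parameter indices as module constants (compile-time for numba)
for _n, _i in P_INDEX.items():
    globals()["P_" + _n.upper()] = _i
for _n, _i in IX.items():
    globals()["S_" + _n.upper()] = _i
for _n, _i in OX.items():
    globals()["O_" + _n.upper()] = _i


@njit(cache=True, fastmath=False)
def _exprel(x):
    # x / (exp(x) - 1), stable near 0
    if abs(x) < 1e-7:
        return 1.0 - 0.5 * x
    return x / (math.exp(x) - 1.0)


@njit(cache=True)
def rhs(t, y, p, istim, clamp_on, clamp_t0, clamp_dt, clamp_v, dy, out):
    """Fill dy (state derivatives) and out (derived outputs). Returns dy."""
    v = y[S_V]
    na_myo = y[S_NA_MYO]
    na_sl = y[S_NA_SL]
    k_i = y[S_K_I]
    ca_myo = y[S_CA_MYO]
    ca_sl = y[S_CA_SL]
    ca_dyad = y[S_CA_DYAD]
    ca_sr = y[S_CA_SR]

    vfrt = v * FRT
    vffrt = v * FARADAY * FRT

    nao = p[P_NAO]
    cao = p[P_CAO]
    ko = p[P_KO]

    e_na = math.log(nao / na_sl) / FRT
    e_k = math.log(ko / k_i) / FRT
    e_ks = math.log((ko + 0.01833 * nao) / (k_i + 0.01833 * na_myo)) / FRT
    e_cl = -math.log(p[P_CLO] / p[P_CLI]) / FRT

    # ------------------------------------------------------------------ CaMKII
    camkt = y[S_CAMK_TRAP]
    camkb = p[P_CAMKO] * (1.0 - camkt) / (1.0 + p[P_KMCAM] / ca_dyad)
    camka = camkb + camkt
    dy[S_CAMK_TRAP] = p[P_ACAMK] * camkb * camka - p[P_BCAMK] * camkt
    fcamk = camka / (camka + p[P_KMCAMK])

    # --------------------------------------------------------- beta-adrenergic
    ag = p[P_AGONIST]
    dy[S_A_PKA] = (ag - y[S_A_PKA]) / p[P_TAU_CAMP]
    apka = y[S_A_PKA]
    dy[S_P_ICAL] = (apka - y[S_P_ICAL]) / p[P_TAU_PHOS]
    dy[S_P_IKS] = (apka - y[S_P_IKS]) / p[P_TAU_PHOS]
    dy[S_P_PLB] = (apka - y[S_P_PLB]) / (0.8 * p[P_TAU_PHOS])
    dy[S_P_RYR] = (apka - y[S_P_RYR]) / p[P_TAU_PHOS]
    dy[S_P_INAK] = (apka - y[S_P_INAK]) / p[P_TAU_PHOS]
    dy[S_P_TNI] = (apka - y[S_P_TNI]) / p[P_TAU_PHOS]
    p_ical = y[S_P_ICAL]
    p_iks = y[S_P_IKS]
    p_plb = y[S_P_PLB]
    p_ryr = y[S_P_RYR]
    p_inak = y[S_P_INAK]
    p_tni = y[S_P_TNI]

    # ------------------------------------------------------------------- INa
    m = y[S_M]
    hf = y[S_HF]
    hs = y[S_HS]
    jg = y[S_J]
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    dy[S_M] = (mss - m) / tm
    dy[S_HF] = (hss - hf) / thf
    dy[S_HS] = (hss - hs) / ths
    dy[S_J] = (hss - jg) / tj
    h = 0.99 * hf + 0.01 * hs
    ina = p[P_GNA] * m * m * m * h * jg * (v - e_na)

    # ------------------------------------------------------------------ INaL
    ml = y[S_ML]
    hl = y[S_HL]
    hlp = y[S_HLP]
    mlss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    hlss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    hlpss = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    dy[S_ML] = (mlss - ml) / tm
    dy[S_HL] = (hlss - hl) / 200.0
    dy[S_HLP] = (hlpss - hlp) / 600.0
    inal = p[P_GNAL] * ml * ((1.0 - fcamk) * hl + fcamk * hlp) * (v - e_na)

    # ------------------------------------------------------------------- Ito
    a = y[S_A]
    i_f = y[S_IF_]
    i_s = y[S_IS_]
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.41) / 29.38)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.38)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tif = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tis = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    aif = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    dy[S_A] = (ass - a) / ta
    dy[S_IF_] = (iss - i_f) / tif
    dy[S_IS_] = (iss - i_s) / tis
    ito = p[P_GTO] * a * (aif * i_f + (1.0 - aif) * i_s) * (v - e_k)

    # ------------------------------------------------------------------ ICaL
    d = y[S_D]
    ff = y[S_FF]
    fs = y[S_FS]
    fca = y[S_FCA]
    jca = y[S_JCA]
    dshift = p[P_C_PKA_DSHIFT] * p_ical
    dss = 1.0 / (1.0 + math.exp(-(v + 3.94 + dshift) / 4.23))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * math.exp(-(v + 5.0) / 4.0)
                          + 3.5e-5 * math.exp((v + 5.0) / 6.0))
    dy[S_D] = (dss - d) / td
    dy[S_FF] = (fss - ff) / tff
    dy[S_FS] = (fss - fs) / tfs
    fv = 0.75 * ff + 0.25 * fs
    # calcium-dependent inactivation gate, driven by dyadic calcium
    cr = ca_dyad / p[P_KM_CDI]
    cr2 = cr * cr
    fcass = 1.0 / (1.0 + cr2)
    tfca = p[P_TAU_FCA_MIN] + p[P_TAU_FCA_REC] / (1.0 + cr2)
    dy[S_FCA] = (fcass - fca) / tfca
    # slow recovery gate (refractoriness of the channel population)
    jcass = p[P_JCA_FLOOR] + (1.0 - p[P_JCA_FLOOR]) \
        / (1.0 + math.exp((v - p[P_VHALF_JCA]) / p[P_SLOPE_JCA]))
    dy[S_JCA] = (jcass - jca) / p[P_TAU_JCA]

    pca_eff = (p[P_PCA] * (1.0 + p[P_C_PKA_ICAL] * p_ical)
               * (1.0 + p[P_C_CAMK_ICAL] * fcamk))
    # a small channel fraction escapes CDI and slow refractoriness
    w = p[P_W_CDI_ESCAPE]
    po = d * fv * ((1.0 - w) * fca * jca + w)
    ex2 = math.exp(2.0 * vfrt)
    # GHK driving force with activity coefficients 0.341 in/out
    if abs(vfrt) < 1e-6:
        # limit: 4*vffrt*(gi*ca*e2 - go*cao)/(e2-1) -> 2*F*(gi*ca-go*cao) at v=0
        phica_d = 2.0 * FARADAY * (0.341 * ca_dyad - 0.341 * cao)
        phica_sl = 2.0 * FARADAY * (0.341 * ca_sl - 0.341 * cao)
        phina = FARADAY * (0.75 * na_sl - 0.75 * nao)
        phik = FARADAY * (0.75 * k_i - 0.75 * ko)
    else:
        phica_d = 4.0 * vffrt * (0.341 * ca_dyad * ex2 - 0.341 * cao) / (ex2 - 1.0)
        phica_sl = 4.0 * vffrt * (0.341 * ca_sl * ex2 - 0.341 * cao) / (ex2 - 1.0)
        ex1 = math.exp(vfrt)
        phina = vffrt * (0.75 * na_sl * ex1 - 0.75 * nao) / (ex1 - 1.0)
        phik = vffrt * (0.75 * k_i * ex1 - 0.75 * ko) / (ex1 - 1.0)
    fd = p[P_FRAC_ICAL_DYAD]
    ical_d = pca_eff * po * phica_d * fd
    ical_sl = pca_eff * po * phica_sl * (1.0 - fd)
    ical = ical_d + ical_sl
    icana = p[P_REL_PCANA] * pca_eff * po * phina
    icak = p[P_REL_PCAK] * pca_eff * po * phik

    # ------------------------------------------------------------------- IKr
    xrf = y[S_XRF]
    xrs = y[S_XRS]
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    dy[S_XRF] = (xrss - xrf) / txrf
    dy[S_XRS] = (xrss - xrs) / txrs
    xr = axrf * xrf + (1.0 - axrf) * xrs
    rkr = 1.0 / ((1.0 + math.exp((v + 55.0) / 75.0))
                 * (1.0 + math.exp((v - 10.0) / 30.0)))
    ikr = p[P_GKR] * math.sqrt(ko / 5.4) * xr * rkr * (v - e_k)

    # ------------------------------------------------------------------- IKs
    xs1 = y[S_XS1]
    xs2 = y[S_XS2]
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    dy[S_XS1] = (xs1ss - xs1) / txs1
    dy[S_XS2] = (xs1ss - xs2) / txs2
    ksca = 1.0 + 0.6 / (1.0 + math.pow(3.8e-5 / ca_myo, 1.4))
    iks = (p[P_GKS] * (1.0 + p[P_C_PKA_IKS] * p_iks)
           * ksca * xs1 * xs2 * (v - e_ks))

    # ------------------------------------------------------------------- IK1
    dvk = v - e_k
    ak1 = 4.094 / (1.0 + math.exp(0.1217 * (dvk - 49.934)))
    bk1 = (15.72 * math.exp(0.0674 * (dvk - 3.257))
           + math.exp(0.0618 * (dvk - 594.31))) \
        / (1.0 + math.exp(-0.1629 * (dvk + 14.207)))
    k1ss = ak1 / (ak1 + bk1)
    ik1 = p[P_GK1] * math.sqrt(ko / 5.4) * k1ss * dvk

    # ------------------------------------------------------------------ INaCa
    eta = p[P_ETA_NCX]
    ksat = p[P_KSAT]
    kmcai = p[P_KMCAI]
    kmcao = p[P_KMCAO]
    kmnai = p[P_KMNAI]
    kmnao = p[P_KMNAO]
    kdact = p[P_KDACT]
    efwd = math.exp(eta * vfrt)
    erev = math.exp((eta - 1.0) * vfrt)
    na3o = nao * nao * nao

    # subsarcolemmal face
    ka_sl = 1.0 / (1.0 + (kdact / ca_sl) * (kdact / ca_sl))
    na3i = na_sl * na_sl * na_sl
    top = efwd * na3i * cao - erev * na3o * ca_sl
    den = (kmcai * na3o * (1.0 + (na_sl / kmnai) ** 3)
           + kmnao ** 3 * ca_sl * (1.0 + ca_sl / kmcai)
           + kmcao * na3i + na3i * cao + na3o * ca_sl)
    inaca_sl = (1.0 - p[P_FRAC_NCX_DYAD]) * p[P_GNCX] * ka_sl * top \
        / (den * (1.0 + ksat * erev))
    # dyadic face (senses dyadic calcium)
    ka_d = 1.0 / (1.0 + (kdact / ca_dyad) * (kdact / ca_dyad))
    top_d = efwd * na3i * cao - erev * na3o * ca_dyad
    den_d = (kmcai * na3o * (1.0 + (na_sl / kmnai) ** 3)
             + kmnao ** 3 * ca_dyad * (1.0 + ca_dyad / kmcai)
             + kmcao * na3i + na3i * cao + na3o * ca_dyad)
    inaca_d = p[P_FRAC_NCX_DYAD] * p[P_GNCX] * ka_d * top_d \
        / (den_d * (1.0 + ksat * erev))
    inaca = inaca_sl + inaca_d

    # ------------------------------------------------------------------ INaK
    sigma = (math.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vfrt)
                  + 0.0365 * sigma * math.exp(-vfrt))
    fna = 1.0 / (1.0 + math.pow(p[P_KMNAINAK] / na_sl, 1.5))
    inak = (p[P_PNAK] * (1.0 + p[P_C_PKA_INAK] * p_inak)
            * fnak * fna * ko / (ko + p[P_KMKO]))

    # ------------------------------------------------------- small currents
    ipca = p[P_GPCA] * ca_sl / (ca_sl + 5.0e-4)
    inab = p[P_GNAB] * (v - e_na)
    icab = p[P_PCAB] * phica_sl
    ikb = p[P_GKB] * (v - e_k) / (1.0 + math.exp(-(v - 14.48) / 18.34))
    iclca = p[P_GCLCA] * (v - e_cl) / (1.0 + p[P_KDCLCA] / ca_sl)
    iclb = p[P_GCLB] * (v - e_cl)

    # ------------------------------------------------------------------- RyR
    r = y[S_RYR_R]
    o = y[S_RYR_O]
    ii = y[S_RYR_I]
    ri = 1.0 - r - o - ii
    kcasr = p[P_MAXSR] - (p[P_MAXSR] - p[P_MINSR]) \
        / (1.0 + math.pow(p[P_EC50SR] / ca_sr, p[P_HSR]))
    ryr_sens = (1.0 + p[P_C_PKA_RYR] * p_ryr) * (1.0 + p[P_C_CAMK_RYR] * fcamk)
    ko_eff = p[P_KO_RYR] * ryr_sens / kcasr
    ki_eff = p[P_KI_RYR] * kcasr
    cad2 = ca_dyad * ca_dyad
    # store-overload-dependent opening: above a free-SR threshold the
    # release channels self-trigger even at diastolic dyadic calcium
    so = (ca_sr - p[P_CASR_SO_THR]) * p[P_SO_SCALE]
    if so > 0.0:
        cad2 = cad2 + so * so
    # calcium-induced refractoriness: recovery from the inactivated and
    # refractory pools requires dyadic calcium to return to diastolic levels
    kref = ca_dyad / p[P_KM_REFRAC]
    kim_eff = p[P_KIM] / (1.0 + kref * kref)
    dy[S_RYR_R] = (kim_eff * ri - ki_eff * ca_dyad * r) \
        - (ko_eff * cad2 * r - p[P_KOM] * o)
    dy[S_RYR_O] = (ko_eff * cad2 * r - p[P_KOM] * o) \
        - (ki_eff * ca_dyad * o - kim_eff * ii)
    dy[S_RYR_I] = (ki_eff * ca_dyad * o - kim_eff * ii) \
        - (p[P_KOM] * ii - ko_eff * cad2 * ri)

    # ICaL-coupled RyR subset: triggered by dyadic ICaL influx
    trig = -ical_d
    if trig < 0.0:
        trig = 0.0
    t2 = trig * trig
    yss = t2 / (t2 + p[P_TRIG_K] * p[P_TRIG_K])
    dy[S_Y_ICL] = (yss - y[S_Y_ICL]) / p[P_TAU_Y_ON]
    # recovery gate of the coupled subset: inactivated by dyadic calcium,
    # recovering only once the dyad returns to diastolic levels
    c2 = (ca_dyad / p[P_TRIG_K2]) * (ca_dyad / p[P_TRIG_K2])
    y2ss = 1.0 / (1.0 + c2)
    tau_y2 = p[P_TAU_Y2_INACT] + (p[P_TAU_Y2_REC] - p[P_TAU_Y2_INACT]) \
        / (1.0 + c2)
    dy[S_Y2_ICL] = (y2ss - y[S_Y2_ICL]) / tau_y2

    # release fluxes on the SR volume basis (mM/ms)
    dcasr_d = ca_sr - ca_dyad
    jrel_ca_sr = p[P_GREL] * o * dcasr_d
    jrel_icl_sr = p[P_GICL] * y[S_Y_ICL] * y[S_Y2_ICL] * dcasr_d
    jrel_sr = jrel_ca_sr + jrel_icl_sr

    # ------------------------------------------------------------ SERCA/leak
    kmf_eff = p[P_KMF] / ((1.0 + p[P_C_PKA_PLB] * p_plb)
                          * (1.0 + p[P_C_CAMK_JUP] * fcamk))
    hup = p[P_HILL_UP]
    rf = math.pow(ca_myo / kmf_eff, hup)
    rr = math.pow(ca_sr / p[P_KMR], hup)
    jup = p[P_VUP] * (1.0 + p[P_C_PKA_VUP] * p_plb) * (rf - rr) \
        / (1.0 + rf + rr)
    jleak = p[P_GLEAK] * (ca_sr - ca_myo)

    # ------------------------------------------------------------- diffusion
    jd_ds = (ca_dyad - ca_sl) / p[P_TAU_DS]       # dyad-volume basis
    jd_sm = (ca_sl - ca_myo) / p[P_TAU_SM]        # sl-volume basis
    jd_na = (na_sl - na_myo) / p[P_TAU_NA]        # sl-volume basis

    # --------------------------------------------------------------- buffers
    dbcam = p[P_KON_CAM] * ca_myo * (p[P_BMAX_CAM] - y[S_B_CAM]) \
        - p[P_KOFF_CAM] * y[S_B_CAM]
    dy[S_B_CAM] = dbcam
    dbsll_sl = p[P_KON_SLL] * ca_sl * (p[P_BMAX_SLL_SL] - y[S_B_SLL_SL]) \
        - p[P_KOFF_SLL] * y[S_B_SLL_SL]
    dy[S_B_SLL_SL] = dbsll_sl
    dbslh_sl = p[P_KON_SLH] * ca_sl * (p[P_BMAX_SLH_SL] - y[S_B_SLH_SL]) \
        - p[P_KOFF_SLH] * y[S_B_SLH_SL]
    dy[S_B_SLH_SL] = dbslh_sl
    dbsll_d = p[P_KON_SLL] * ca_dyad * (p[P_BMAX_SLL_D] - y[S_B_SLL_D]) \
        - p[P_KOFF_SLL] * y[S_B_SLL_D]
    dy[S_B_SLL_D] = dbsll_d
    dbslh_d = p[P_KON_SLH] * ca_dyad * (p[P_BMAX_SLH_D] - y[S_B_SLH_D]) \
        - p[P_KOFF_SLH] * y[S_B_SLH_D]
    dy[S_B_SLH_D] = dbslh_d
    dbcsqn = p[P_KON_CSQN] * ca_sr * (p[P_BMAX_CSQN] - y[S_B_CSQN]) \
        - p[P_KOFF_CSQN] * y[S_B_CSQN]
    dy[S_B_CSQN] = dbcsqn

    # ------------------------------------------------------------ contraction
    ca50_eff = p[P_CA50] * (1.0 + p[P_BETA1] * (p[P_LAM] - 1.0)) \
        * (1.0 + p[P_C_PKA_CA50] * p_tni)
    ktrpn_eff = p[P_KTRPN] * (1.0 + p[P_C_PKA_KTRPN] * p_tni)
    catrpn = y[S_CA_TRPN]
    if catrpn < 1e-8:
        catrpn = 1e-8
    crat = math.pow(ca_myo / ca50_eff, p[P_NTRPN])
    dcatrpn = ktrpn_eff * (crat * (1.0 - catrpn) - catrpn)
    dy[S_CA_TRPN] = dcatrpn

    tmb = y[S_TM_B]
    xw = y[S_XB_W]
    xs = y[S_XB_S]
    xu = 1.0 - tmb - xw - xs
    ctn_pow = math.pow(catrpn, p[P_NTM] * 0.5)
    inv_ctn = 1.0 / ctn_pow
    if inv_ctn > 100.0:
        inv_ctn = 100.0
    # PKA phosphorylation promotes crossbridge recruitment (faster
    # tropomyosin unblocking) in addition to faster cycling
    ktmu_eff = p[P_KTMU] * (1.0 + p[P_C_PKA_XB] * p_tni)
    dy[S_TM_B] = p[P_KTMB] * inv_ctn * xu - ktmu_eff * ctn_pow * tmb
    kuw_eff = p[P_KUW] * (1.0 + p[P_C_PKA_XB] * p_tni)
    kws_eff = p[P_KWS] * (1.0 + p[P_C_PKA_XB] * p_tni)
    kwu = kuw_eff * (1.0 / p[P_RW] - 1.0) - kws_eff
    ksu = kws_eff * p[P_RW] * (1.0 / p[P_RS] - 1.0)
    dy[S_XB_W] = kuw_eff * xu - kws_eff * xw - kwu * xw
    dy[S_XB_S] = kws_eff * xw - ksu * xs
    lam = p[P_LAM]
    lam_c = lam
    if lam_c > 1.2:
        lam_c = 1.2
    lmin = lam_c
    if lmin > 0.87:
        lmin = 0.87
    hlam = 1.0 + p[P_BETA0] * (lam_c + lmin - 1.87)
    if hlam < 0.0:
        hlam = 0.0
    tension = hlam * p[P_TREF] / p[P_RS] * xs

    # ------------------------------------------------- concentration balances
    c_na_sl = ACAP / (FARADAY * V_SL)
    c_ca_sl = ACAP / (2.0 * FARADAY * V_SL)
    c_ca_d = ACAP / (2.0 * FARADAY * V_DYAD)
    c_k = ACAP / (FARADAY * V_K)

    dy[S_NA_SL] = -(ina + inal + inab + icana
                    + 3.0 * inaca_sl + 3.0 * inaca_d + 3.0 * inak) * c_na_sl \
        - jd_na
    dy[S_NA_MYO] = jd_na * (V_SL / V_MYO)
    dy[S_K_I] = -(ito + ikr + iks + ik1 + ikb + icak - 2.0 * inak + istim) * c_k

    dy[S_CA_DYAD] = -(ical_d - 2.0 * inaca_d) * c_ca_d \
        + jrel_sr * (V_SR / V_DYAD) - jd_ds - dbsll_d - dbslh_d
    dy[S_CA_SL] = -(ical_sl + icab + ipca - 2.0 * inaca_sl) * c_ca_sl \
        + jd_ds * (V_DYAD / V_SL) - jd_sm - dbsll_sl - dbslh_sl
    dy[S_CA_MYO] = jd_sm * (V_SL / V_MYO) + jleak - jup \
        - dbcam - p[P_TRPN_TOT] * dcatrpn
    dy[S_CA_SR] = (jup - jleak) * (V_MYO / V_SR) - jrel_sr - dbcsqn

    # ------------------------------------------------------------ membrane V
    itot = (ina + inal + ito + ical + icana + icak + ikr + iks + ik1
            + inaca + inak + ipca + inab + icab + ikb + iclca + iclb + istim)
    if clamp_on != 0:
        # AP-clamp mode: V relaxes rapidly onto the supplied waveform
        tw = (t - clamp_t0) / clamp_dt
        iw = int(tw)
        if iw < 0:
            vtarget = clamp_v[0]
        elif iw >= clamp_v.shape[0] - 1:
            vtarget = clamp_v[clamp_v.shape[0] - 1]
        else:
            frac = tw - iw
            vtarget = clamp_v[iw] * (1.0 - frac) + clamp_v[iw + 1] * frac
        dy[S_V] = (vtarget - v) / 0.05
    else:
        dy[S_V] = -itot

    # ------------------------------------------------------ derived outputs
    out[O_INA] = ina
    out[O_INAL] = inal
    out[O_ITO] = ito
    out[O_ICAL] = ical
    out[O_ICAL_D] = ical_d
    out[O_ICAL_SL] = ical_sl
    out[O_ICANA] = icana
    out[O_ICAK] = icak
    out[O_IKR] = ikr
    out[O_IKS] = iks
    out[O_IK1] = ik1
    out[O_INACA] = inaca
    out[O_INACA_D] = inaca_d
    out[O_INACA_SL] = inaca_sl
    out[O_INAK] = inak
    out[O_IPCA] = ipca
    out[O_INAB] = inab
    out[O_ICAB] = icab
    out[O_IKB] = ikb
    out[O_ICLCA] = iclca
    out[O_ICLB] = iclb
    out[O_ISTIM] = istim
    out[O_JREL] = jrel_sr * (V_SR / V_MYO)
    out[O_JREL_CA] = jrel_ca_sr * (V_SR / V_MYO)
    out[O_JREL_ICL] = jrel_icl_sr * (V_SR / V_MYO)
    out[O_JUP] = jup
    out[O_JLEAK] = jleak
    # sarcolemmal Ca fluxes on the myoplasm volume basis (mM/ms, influx > 0)
    out[O_JNCX_CA] = 2.0 * inaca * ACAP / (2.0 * FARADAY * V_MYO)
    out[O_JPCA_CA] = -ipca * ACAP / (2.0 * FARADAY * V_MYO)
    out[O_JCAL_CA] = -ical * ACAP / (2.0 * FARADAY * V_MYO)
    out[O_JCAB_CA] = -icab * ACAP / (2.0 * FARADAY * V_MYO)
    out[O_TENSION] = tension
    out[O_CAMK_ACTIVE] = camka
    out[O_E_NA] = e_na
    out[O_E_K] = e_k
    out[O_E_KS] = e_ks
    out[O_E_CL] = e_cl
    return dy


_DUMMY_CLAMP = np.zeros(2)


def rhs_py(t, y, p, istim=0.0, clamp=None):
    """Convenience wrapper: returns (dy, out) as fresh arrays.

    ``clamp`` is an optional tuple (t0, dt, v_array) for AP-clamp mode.
    """
    dy = np.zeros(N_STATES)
    out = np.zeros(N_OUT)
    if clamp is None:
        rhs(t, y, p, istim, 0, 0.0, 1.0, _DUMMY_CLAMP, dy, out)
    else:
        t0, dt, varr = clamp
        rhs(t, y, p, istim, 1, t0, dt, np.asarray(varr, dtype=np.float64),
            dy, out)
    return dy, out
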