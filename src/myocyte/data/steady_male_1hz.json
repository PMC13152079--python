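{
 "v": -88.76893509083533,
 "m": 0.006798786388636258,
 "hf": 0.7239881812837754,
 "hs": 0.7239499931563403,
 "j": 0.7237413600522863,
 "ml": 0.00016273882355116742,
 "hl": 0.5196908100721728,
 "hlp": 0.2732751664702667,
 "a": 0.0009506565541276182,
 "if_": 0.9996101166278274,
 "is_": 0.5669229809491052,
 "d": 1.9526312871848544e-09,
 "ff": 0.9999999925829728,
 "fs": 0.9138011577067915,
 "fca": 0.9984361611613217,
 "jca": 0.9913429096727533,
 "xrf": 7.285129306221152e-06,
 "xrs": 0.4537499512140524,
 "xs1": 0.3434785247425962,
 "xs2": 0.0001770512689922226,
 "ryr_r": 0.3675547601284513,
 "ryr_o": 2.763007769814109e-06,
 "ryr_i": 4.754204243979106e-06,
 "y_icl": 1.4775594975778394e-12,
 "y2_icl": 0.9261033862528011,
 "na_myo": 8.450462992680883,
 "na_sl": 8.446183453433246,
 "k_i": 143.55121976985103,
 "ca_myo": 6.74616483084256e-05,
 "ca_sl": 0.0001901312687232579,
 "ca_dyad": 0.00019680542979722034,
 "ca_sr": 1.1095648357861445,
 "b_cam": 0.00047716288861563664,
 "b_sll_sl": 0.01730607764779462,
 "b_slh_sl": 0.11737003439176971,
 "b_sll_d": 0.0596839915297235,
 "b_slh_d": 0.47962545632938514,
 "b_csqn": 1.530815925484552,
 "camk_trap": 0.30102855993803146,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.0328820406891776,
 "tm_b": 0.9814535054708188,
 "xb_w": 0.005036947942854784,
 "xb_s": 0.008802521613358351
}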