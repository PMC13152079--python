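{
 "v": -88.57090607509505,
 "m": 0.0069356008705279285,
 "hf": 0.7174393255753871,
 "hs": 0.7174360711077656,
 "j": 0.7174189605297953,
 "ml": 0.0001689764188700189,
 "hl": 0.5316910724470802,
 "hlp": 0.32039380589398353,
 "a": 0.0009634223522172647,
 "if_": 0.9995964782968264,
 "is_": 0.8650917522305833,
 "d": 2.04615469939377e-09,
 "ff": 0.9999999921780505,
 "fs": 0.9610761758170879,
 "fca": 0.9998954194310181,
 "jca": 0.9996795682503692,
 "xrf": 7.369994433956706e-06,
 "xrs": 0.16521473988859867,
 "xs1": 0.17508181740991158,
 "xs2": 0.00018090205045016904,
 "ryr_r": 0.4078115710570338,
 "ryr_o": 6.928512469563021e-07,
 "ryr_i": 1.0060952844796612e-06,
 "y_icl": 1.5769691342549537e-12,
 "y2_icl": 0.9737831733535228,
 "na_myo": 5.131548809617461,
 "na_sl": 5.128979973880469,
 "k_i": 146.30043285354745,
 "ca_myo": 5.9411365466248875e-05,
 "ca_sl": 0.00012879408798677891,
 "ca_dyad": 0.0001291068692454745,
 "ca_sr": 0.7626052562666765,
 "b_cam": 0.00042061923337153407,
 "b_sll_sl": 0.011772848187028452,
 "b_slh_sl": 0.09024734121686992,
 "b_sll_d": 0.03933761799893276,
 "b_slh_d": 0.3616886259153299,
 "b_csqn": 1.314264204248719,
 "camk_trap": 0.06513708966879335,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.02625473066975328,
 "tm_b": 0.9917610844076582,
 "xb_w": 0.0030934442209998862,
 "xb_s": 0.0019795469454503022
}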