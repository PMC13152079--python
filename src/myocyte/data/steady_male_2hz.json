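{
 "v": -88.61542674199546,
 "m": 0.006904617247986597,
 "hf": 0.718917899730975,
 "hs": 0.7187508129523901,
 "j": 0.7176456467998313,
 "ml": 0.00016755409061553064,
 "hl": 0.4603513389884585,
 "hlp": 0.22272789300070917,
 "a": 0.0009605809430811924,
 "if_": 0.9995990887804781,
 "is_": 0.37318596469499915,
 "d": 2.025015864058151e-09,
 "ff": 0.9999999922563881,
 "fs": 0.8805343958359066,
 "fca": 0.9648246650275889,
 "jca": 0.9557180361654952,
 "xrf": 0.00023540704955666474,
 "xrs": 0.6613742064157679,
 "xs1": 0.4030187526967856,
 "xs2": 0.00018083712783505896,
 "ryr_r": 0.20355795173880442,
 "ryr_o": 3.618916002156438e-06,
 "ryr_i": 1.4159076725770946e-05,
 "y_icl": 1.3722428240370015e-12,
 "y2_icl": 0.7585401743183302,
 "na_myo": 12.05573417666277,
 "na_sl": 12.050185795883662,
 "k_i": 140.32131121101366,
 "ca_myo": 6.045164681398955e-05,
 "ca_sl": 0.0003073478728249417,
 "ca_dyad": 0.000326486997114526,
 "ca_sr": 0.9479648012348065,
 "b_cam": 0.0004296781964897782,
 "b_sll_sl": 0.027752071105170334,
 "b_slh_sl": 0.1541217926367186,
 "b_sll_d": 0.09813038756908968,
 "b_slh_d": 0.6345551917107575,
 "b_csqn": 1.4417983000742227,
 "camk_trap": 0.4720956176085675,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.02969526655391591,
 "tm_b": 0.9426604390884674,
 "xb_w": 0.016879620190824077,
 "xb_s": 0.03522892677397649
}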