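{
 "v": -88.7479841514167,
 "m": 0.006813135885798047,
 "hf": 0.7232993375575282,
 "hs": 0.7232278875818317,
 "j": 0.7228160778925098,
 "ml": 0.00016338782156441443,
 "hl": 0.503959721946596,
 "hlp": 0.2577096448198744,
 "a": 0.0009520094806399667,
 "if_": 0.9996085802713011,
 "is_": 0.48888944787500627,
 "d": 1.9623833087238895e-09,
 "ff": 0.9999999925377951,
 "fs": 0.9093270102025758,
 "fca": 0.9895547335118505,
 "jca": 0.9849532596280347,
 "xrf": 1.2474434351812699e-05,
 "xrs": 0.5511406110637149,
 "xs1": 0.35565021192867413,
 "xs2": 0.00017758522782106652,
 "ryr_r": 0.2702554642567824,
 "ryr_o": 2.5348410450912225e-06,
 "ryr_i": 6.844496643983822e-06,
 "y_icl": 1.4574481188474207e-12,
 "y2_icl": 0.8737428591869403,
 "na_myo": 10.445869506200728,
 "na_sl": 10.440755786988824,
 "k_i": 141.77450806716678,
 "ca_myo": 5.6819887860136234e-05,
 "ca_sl": 0.00023032628865157719,
 "ca_dyad": 0.00024182352576189553,
 "ca_sr": 0.9437203112883648,
 "b_cam": 0.00040270067919515273,
 "b_sll_sl": 0.02090796337014807,
 "b_slh_sl": 0.1318938827389778,
 "b_sll_d": 0.07311175735447797,
 "b_slh_d": 0.5422008054055891,
 "b_csqn": 1.4392169315203616,
 "camk_trap": 0.3907465368692721,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.02462819879981562,
 "tm_b": 0.9729000286908367,
 "xb_w": 0.005807168513691774,
 "xb_s": 0.017969869644245618
}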