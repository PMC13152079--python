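{
 "v": -89.21813238375002,
 "m": 0.006498295995960554,
 "hf": 0.7384907488941299,
 "hs": 0.7384384675176718,
 "j": 0.7381453116539647,
 "ml": 0.00014942974169735316,
 "hl": 0.5218737963182932,
 "hlp": 0.26205040896772636,
 "a": 0.0009223047637981207,
 "if_": 0.9996395506232878,
 "is_": 0.5251422715173686,
 "d": 1.163772321780479e-08,
 "ff": 0.9999999934304936,
 "fs": 0.888121787479589,
 "fca": 0.99701635543404,
 "jca": 0.9849028830576702,
 "xrf": 7.379770969411034e-06,
 "xrs": 0.4830600016874082,
 "xs1": 0.3702382232892059,
 "xs2": 0.00016841875436852903,
 "ryr_r": 0.41779624609430277,
 "ryr_o": 7.40651090722535e-06,
 "ryr_i": 1.0320739386042302e-05,
 "y_icl": 1.8697172789250242e-10,
 "y2_icl": 0.9090667942198105,
 "na_myo": 7.683374568291365,
 "na_sl": 7.678133707637139,
 "k_i": 143.9831879392306,
 "ca_myo": 6.647474576949534e-05,
 "ca_sl": 0.0002029918761507563,
 "ca_dyad": 0.0002137000511240978,
 "ca_sr": 1.8193162936724585,
 "b_cam": 0.0004702337320278328,
 "b_sll_sl": 0.01846003417372343,
 "b_slh_sl": 0.12220429953526851,
 "b_sll_d": 0.06472959849074875,
 "b_slh_d": 0.5040013349447316,
 "b_csqn": 1.7826843449275989,
 "camk_trap": 0.34919437178558244,
 "a_pka": 0.9999999999999867,
 "p_ical": 0.9999999999999502,
 "p_iks": 0.9999999999999502,
 "p_plb": 0.9999999999999589,
 "p_ryr": 0.9999999999999502,
 "p_inak": 0.9999999999999502,
 "p_tni": 0.9999999999999502,
 "ca_trpn": 0.01776481213451283,
 "tm_b": 0.9808104289644206,
 "xb_w": 0.007197503795091378,
 "xb_s": 0.004772433600224502
}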