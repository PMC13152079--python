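{
 "v": -88.86905030481053,
 "m": 0.006730640941316243,
 "hf": 0.7272632486661733,
 "hs": 0.7272247113565575,
 "j": 0.7270111465359518,
 "ml": 0.00015967345509918757,
 "hl": 0.519377247404659,
 "hlp": 0.2681838183949086,
 "a": 0.0009442623202500513,
 "if_": 0.9996168870637694,
 "is_": 0.5496775932417944,
 "d": 1.906960271273333e-09,
 "ff": 0.9999999927811226,
 "fs": 0.8463859293806932,
 "fca": 0.9986156057711242,
 "jca": 0.9889730258854919,
 "xrf": 7.327112753813894e-06,
 "xrs": 0.48393747216470673,
 "xs1": 0.39907479042864186,
 "xs2": 0.00017508101546469994,
 "ryr_r": 0.27410245349423823,
 "ryr_o": 9.621430879389345e-07,
 "ryr_i": 2.5480033213428333e-06,
 "y_icl": 1.357901615895903e-12,
 "y2_icl": 0.9327808461680619,
 "na_myo": 7.714938854690786,
 "na_sl": 7.7110171812845545,
 "k_i": 144.40752245365093,
 "ca_myo": 4.4374217854663094e-05,
 "ca_sl": 0.0001760441470659232,
 "ca_dyad": 0.00018286230890219617,
 "ca_sr": 0.7187022898890855,
 "b_cam": 0.00031489202489192104,
 "b_sll_sl": 0.016042102495023015,
 "b_slh_sl": 0.11208627099700913,
 "b_sll_d": 0.05551815632501612,
 "b_slh_d": 0.4593143695403797,
 "b_csqn": 1.2789200048420672,
 "camk_trap": 0.3009336463106019,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.015743228532083695,
 "tm_b": 0.9940574034207451,
 "xb_w": 0.0015209359323909214,
 "xb_s": 0.002978763437531157
}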