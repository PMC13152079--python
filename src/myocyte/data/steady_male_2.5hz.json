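{
 "v": -88.31684693706515,
 "m": 0.007115181972467517,
 "hf": 0.7088932959094358,
 "hs": 0.7083099065811349,
 "j": 0.7028992870375197,
 "ml": 0.0001773323473340008,
 "hl": 0.37315640340035366,
 "hlp": 0.1786076736535055,
 "a": 0.0009802222794671274,
 "if_": 0.9995761983824504,
 "is_": 0.24212548597516675,
 "d": 2.1738413893601454e-09,
 "ff": 0.999999991563032,
 "fs": 0.8334555442393353,
 "fca": 0.9191912773720742,
 "jca": 0.8557041345618509,
 "xrf": 0.006351649505582811,
 "xrs": 0.7716512470771667,
 "xs1": 0.4679414550355,
 "xs2": 0.0002651683829418243,
 "ryr_r": 0.14458786886523428,
 "ryr_o": 5.789865731059659e-06,
 "ryr_i": 3.425246814009615e-05,
 "y_icl": 1.117060496890606e-12,
 "y2_icl": 0.5646204291589075,
 "na_myo": 12.788236832874677,
 "na_sl": 12.78298776058391,
 "k_i": 139.47842516231924,
 "ca_myo": 8.044435846576838e-05,
 "ca_sl": 0.00043559227585998237,
 "ca_dyad": 0.00046694982555836844,
 "ca_sr": 0.9793562450275464,
 "b_cam": 0.0005762069940073479,
 "b_sll_sl": 0.03899128309529669,
 "b_slh_sl": 0.1807704310316451,
 "b_sll_d": 0.1390079280350176,
 "b_slh_d": 0.74260596724572,
 "b_csqn": 1.4604777425029491,
 "camk_trap": 0.5374225764657128,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.058115795173061424,
 "tm_b": 0.8814269833832447,
 "xb_w": 0.04766146700369147,
 "xb_s": 0.054863710879384665
}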