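{
 "v": -88.05600736041812,
 "m": 0.007304360758934977,
 "hf": 0.6999628157387415,
 "hs": 0.6987979782901332,
 "j": 0.6861273093736341,
 "ml": 0.0001863414976778065,
 "hl": 0.33102486726368063,
 "hlp": 0.1576203601027397,
 "a": 0.0009977608941428176,
 "if_": 0.9995544047415439,
 "is_": 0.19768680796841057,
 "d": 2.3131229820411166e-09,
 "ff": 0.9999999908773205,
 "fs": 0.7903008370436151,
 "fca": 0.8797303201943784,
 "jca": 0.8103464007342465,
 "xrf": 0.01929639016319749,
 "xrs": 0.8165516775742436,
 "xs1": 0.5035959130584879,
 "xs2": 0.0006583342067980905,
 "ryr_r": 0.11631778691881178,
 "ryr_o": 7.717162695974071e-06,
 "ryr_i": 5.8623946195098134e-05,
 "y_icl": 1.0112739381709562e-12,
 "y2_icl": 0.44163501511886055,
 "na_myo": 13.611981522640315,
 "na_sl": 13.606989778695223,
 "k_i": 138.70826263418851,
 "ca_myo": 9.747915383245664e-05,
 "ca_sl": 0.0005438062056399556,
 "ca_dyad": 0.0005855892812148423,
 "ca_sr": 0.9799747772845157,
 "b_cam": 0.000699949422782038,
 "b_sll_sl": 0.048324007971254794,
 "b_slh_sl": 0.1967969745886229,
 "b_sll_d": 0.1729301207023249,
 "b_slh_d": 0.8065712485306948,
 "b_csqn": 1.4608296833074357,
 "camk_trap": 0.5723224650380275,
 "a_pka": 0.0,
 "p_ical": 0.0,
 "p_iks": 0.0,
 "p_plb": 0.0,
 "p_ryr": 0.0,
 "p_inak": 0.0,
 "p_tni": 0.0,
 "ca_trpn": 0.08405833719146645,
 "tm_b": 0.8534081953025522,
 "xb_w": 0.06313391462843308,
 "xb_s": 0.0561346507020256
}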