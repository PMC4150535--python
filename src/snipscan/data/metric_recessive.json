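{
 "model_label": "recessive",
 "poly_coeffs": [
  -0.00011663702818586133,
  0.1067036482882638,
  0.09118535373545189,
  -0.6707284006142936,
  0.6999827183636227,
  -0.2271335842215677
 ],
 "tail_lo_x": 0.17500000000000002,
 "tail_hi_x": 0.8250000000000001,
 "tail_lo_y": 0.01725567620927937,
 "tail_hi_y": 0.00973870469905806,
 "scale": 3344.007993552873,
 "config": {
  "n_replicates": 1000000,
  "n_cases": 1000,
  "n_controls": 1000,
  "penetrances": [
   0.01,
   0.01,
   0.0225
  ],
  "top_fraction": 0.01,
  "bin_width": 0.05,
  "poly_degree": 5,
  "n_tail_bins_excluded": 3,
  "seed": 1,
  "n_used": 993586
 },
 "bin_table": {
  "bin_mid": [
   0.025,
   0.07500000000000001,
   0.125,
   0.17500000000000002,
   0.225,
   0.275,
   0.325,
   0.375,
   0.42500000000000004,
   0.47500000000000003,
   0.525,
   0.5750000000000001,
   0.625,
   0.675,
   0.7250000000000001,
   0.775,
   0.8250000000000001,
   0.875,
   0.925,
   0.9750000000000001
  ],
  "n": [
   382670,
   100410,
   66606,
   50650,
   41467,
   35762,
   31686,
   28406,
   25884,
   24055,
   22217,
   21369,
   19898,
   19468,
   18900,
   18379,
   18791,
   19115,
   20252,
   27601
  ],
  "p_top": [
   3.9198264823477146e-05,
   0.002410118514092222,
   0.010389454403507192,
   0.01725567620927937,
   0.02264451250391878,
   0.027515239639841173,
   0.028498390456352964,
   0.0287967330845596,
   0.02932313398238294,
   0.028975265017667843,
   0.029076833055768105,
   0.0255042351069306,
   0.022464569303447583,
   0.021830696527635092,
   0.018042328042328044,
   0.014690679579955384,
   0.00973870469905806,
   0.006382422181532827,
   0.001629468694449931,
   3.623057135611029e-05
  ]
 }
}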