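{
 "model_label": "multiplicative",
 "poly_coeffs": [
  -2.0881618537457627e-05,
  0.20023022749198613,
  -0.4433204885166662,
  0.30388431879001393,
  -0.08019825406698852,
  0.01943783999023707
 ],
 "tail_lo_x": 0.17500000000000002,
 "tail_hi_x": 0.8250000000000001,
 "tail_lo_y": 0.02263069665899965,
 "tail_hi_y": 0.004408974215872307,
 "scale": 3592.094804186867,
 "config": {
  "n_replicates": 1000000,
  "n_cases": 1000,
  "n_controls": 1000,
  "penetrances": [
   0.01,
   0.015,
   0.0225
  ],
  "top_fraction": 0.01,
  "bin_width": 0.05,
  "poly_degree": 5,
  "n_tail_bins_excluded": 3,
  "seed": 1,
  "n_used": 994019
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
   383311,
   101952,
   67538,
   51302,
   42195,
   36068,
   31543,
   28506,
   25674,
   23895,
   22206,
   20996,
   19992,
   19222,
   18516,
   18139,
   17918,
   18954,
   19798,
   26294
  ],
  "p_top": [
   0.0001747927922757239,
   0.007003295668549906,
   0.016109449495099057,
   0.02263069665899965,
   0.025832444602441048,
   0.028834423866030832,
   0.027169261008781663,
   0.026345330807549288,
   0.026057490067772845,
   0.024314710190416405,
   0.022021075385031074,
   0.018670222899599923,
   0.015706282513005203,
   0.012901883258765998,
   0.008965219269820695,
   0.007166877997684547,
   0.004408974215872307,
   0.003376595969188562,
   0.0013132639660571775,
   0.0005704723511067163
  ]
 }
}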