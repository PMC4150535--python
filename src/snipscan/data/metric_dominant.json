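{
 "model_label": "dominant",
 "poly_coeffs": [
  -0.00019471046605828548,
  0.11684640428132675,
  0.08802429275190159,
  -0.7748632756742069,
  0.8777393453202245,
  -0.3076835009677661
 ],
 "tail_lo_x": 0.17500000000000002,
 "tail_hi_x": 0.8250000000000001,
 "tail_lo_y": 0.017727255417190297,
 "tail_hi_y": 0.009325441143622961,
 "scale": 3294.192632542401,
 "config": {
  "n_replicates": 1000000,
  "n_cases": 1000,
  "n_controls": 1000,
  "penetrances": [
   0.01,
   0.0225,
   0.0225
  ],
  "top_fraction": 0.01,
  "bin_width": 0.05,
  "poly_degree": 5,
  "n_tail_bins_excluded": 3,
  "seed": 1,
  "n_used": 994393
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
   383191,
   103342,
   68747,
   52518,
   43004,
   36086,
   31809,
   28275,
   25921,
   23700,
   22298,
   20639,
   19432,
   18954,
   18288,
   17819,
   17908,
   18140,
   19128,
   25194
  ],
  "p_top": [
   0.00014614121939189595,
   0.0025739776663892705,
   0.008538554409646966,
   0.017727255417190297,
   0.02383499209375872,
   0.030399600953278278,
   0.02813669087365211,
   0.031370468611847925,
   0.028162493730951737,
   0.029324894514767934,
   0.027267019463629024,
   0.024129076021125056,
   0.0242383696994648,
   0.019943019943019943,
   0.01755249343832021,
   0.012514731466412257,
   0.009325441143622961,
   0.003914002205071665,
   0.0016206608113759934,
   0.0002778439310947051
  ]
 }
}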