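{
 "version": 1,
 "n_freq_classes": 10,
 "linkage_classes": [
  "nested",
  "disjoint"
 ],
 "training": {
  "n_null": 200,
  "n_alt": 200,
  "seeds": {
   "null": 101,
   "balancing": 102,
   "sweep": 103
  },
  "window_bp": 3000,
  "n_samples": 30,
  "mutation_rate": 1.5e-07
 },
 "weights": {
  "balancing": [
   -0.09779743476667845,
   -0.13401242570244387,
   0.003275926750297573,
   -0.0911025335441073,
   -0.06495240158762404,
   -0.04282123151045507,
   -0.05967844115919571,
   0.02542893057177858,
   -0.05861497500216751,
   0.010864984090408194,
   0.7950833862398601,
   0.5413411928467329,
   -0.06443439913210079,
   -0.07022733410458157,
   -0.06754984331816201,
   -0.0520219473374797,
   -0.0619985955618977,
   -0.014509633841277212,
   -0.06882134680339708,
   0.0
  ],
  "sweep": [
   -0.2890878271562052,
   0.356485728846647,
   -0.1383503026927704,
   -0.07568424129413376,
   -0.130061598819104,
   -0.11760145844271268,
   -0.11112385256577478,
   -0.09291262620774719,
   -0.08733946336928894,
   -0.08822194058507456,
   -0.0729823610763395,
   -0.06655144231928117,
   -0.060648894858004225,
   -0.06419942194751198,
   -0.05820051070684514,
   -0.0475566813155196,
   0.7441662001186024,
   -0.013264209971189607,
   0.34666262707369166,
   0.0
  ]
 }
}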