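{
 "description": "Monte-Carlo calibration of generator dials to mean full-pipeline parallelism at default texture parameters",
 "replicates": 100,
 "seed": 20160623,
 "streak": {
  "kappa": [
   0.0,
   0.25,
   0.5,
   0.75,
   1.0,
   1.5,
   2.0,
   3.0,
   4.0,
   6.0,
   8.0,
   12.0,
   16.0,
   32.0,
   64.0
  ],
  "mean_score": [
   0.0537,
   0.0905,
   0.1614,
   0.201,
   0.259,
   0.3487,
   0.4116,
   0.4833,
   0.5346,
   0.5655,
   0.5848,
   0.6071,
   0.6155,
   0.6311,
   0.6556
  ],
  "sd_score": [
   0.0301,
   0.0368,
   0.0503,
   0.0437,
   0.0586,
   0.0595,
   0.052,
   0.0574,
   0.0514,
   0.0582,
   0.0484,
   0.0593,
   0.0574,
   0.0608,
   0.0668
  ]
 },
 "blob": {
  "n_blobs": [
   3,
   4,
   6,
   9,
   14,
   20,
   30,
   50,
   80
  ],
  "mean_score": [
   0.1102,
   0.0942,
   0.0783,
   0.0593,
   0.0524,
   0.0404,
   0.0393,
   0.0338,
   0.0309
  ],
  "sd_score": [
   0.0781,
   0.0642,
   0.0381,
   0.0352,
   0.0255,
   0.0203,
   0.0172,
   0.0142,
   0.0136
  ],
  "n_undefined": [
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0,
   0
  ]
 }
}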