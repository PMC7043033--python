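{
 "reps": 20000,
 "seed": 20200226,
 "n": [
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  12,
  14,
  16,
  18,
  20,
  25,
  30,
  35,
  40,
  50,
  60,
  80,
  100,
  150,
  200,
  300,
  400,
  500,
  700,
  1000,
  1500,
  2000
 ],
 "alphas": [
  0.001,
  0.005,
  0.01,
  0.02,
  0.05,
  0.1,
  0.15,
  0.2,
  0.3,
  0.4,
  0.5
 ],
 "crit": [
  [
   0.431055,
   0.421018,
   0.412963,
   0.400331,
   0.376702,
   0.34591,
   0.321408,
   0.302454,
   0.284333,
   0.270475,
   0.25739
  ],
  [
   0.44183,
   0.415582,
   0.394994,
   0.374597,
   0.343666,
   0.319413,
   0.303658,
   0.290055,
   0.267003,
   0.247805,
   0.233324
  ],
  [
   0.431047,
   0.388459,
   0.369871,
   0.351085,
   0.322005,
   0.296245,
   0.279885,
   0.267503,
   0.247838,
   0.231855,
   0.216894
  ],
  [
   0.394143,
   0.363268,
   0.349181,
   0.331384,
   0.305022,
   0.280404,
   0.264272,
   0.252441,
   0.234283,
   0.219432,
   0.206727
  ],
  [
   0.387029,
   0.349853,
   0.333216,
   0.315831,
   0.288085,
   0.265646,
   0.250811,
   0.239598,
   0.22139,
   0.207612,
   0.195495
  ],
  [
   0.366338,
   0.336715,
   0.321464,
   0.301491,
   0.276544,
   0.253074,
   0.2391,
   0.228003,
   0.210898,
   0.197274,
   0.185392
  ],
  [
   0.350288,
   0.318478,
   0.301109,
   0.285535,
   0.261507,
   0.239848,
   0.226416,
   0.216381,
   0.200679,
   0.188054,
   0.176382
  ],
  [
   0.330327,
   0.299156,
   0.284048,
   0.265929,
   0.24172,
   0.220857,
   0.208066,
   0.198459,
   0.183915,
   0.172466,
   0.162681
  ],
  [
   0.307133,
   0.280125,
   0.264736,
   0.24768,
   0.225893,
   0.207715,
   0.195619,
   0.186726,
   0.173141,
   0.161601,
   0.151925
  ],
  [
   0.278919,
   0.258522,
   0.246795,
   0.232708,
   0.21253,
   0.195541,
   0.184404,
   0.17553,
   0.162301,
   0.151815,
   0.143104
  ],
  [
   0.277841,
   0.244899,
   0.233825,
   0.222617,
   0.202846,
   0.18569,
   0.175566,
   0.167033,
   0.154583,
   0.144557,
   0.135833
  ],
  [
   0.264897,
   0.235835,
   0.223293,
   0.211371,
   0.192116,
   0.17653,
   0.166513,
   0.159102,
   0.147301,
   0.137636,
   0.12936
  ],
  [
   0.233142,
   0.211086,
   0.199597,
   0.190053,
   0.173485,
   0.159306,
   0.15022,
   0.143592,
   0.132933,
   0.124457,
   0.116751
  ],
  [
   0.212867,
   0.191423,
   0.184476,
   0.174384,
   0.158638,
   0.145667,
   0.137259,
   0.130644,
   0.121335,
   0.113356,
   0.106788
  ],
  [
   0.204783,
   0.17926,
   0.170553,
   0.161763,
   0.147242,
   0.135406,
   0.127676,
   0.12181,
   0.112894,
   0.105568,
   0.099423
  ],
  [
   0.190541,
   0.170172,
   0.161869,
   0.152666,
   0.138556,
   0.127401,
   0.120387,
   0.11495,
   0.106335,
   0.09963,
   0.093543
  ],
  [
   0.172642,
   0.153949,
   0.145303,
   0.136945,
   0.12468,
   0.11437,
   0.107997,
   0.103128,
   0.095643,
   0.089471,
   0.084092
  ],
  [
   0.155692,
   0.140751,
   0.132162,
   0.124951,
   0.113875,
   0.104744,
   0.098594,
   0.094291,
   0.087454,
   0.082086,
   0.077286
  ],
  [
   0.134133,
   0.121592,
   0.115359,
   0.108607,
   0.099221,
   0.091138,
   0.086031,
   0.082068,
   0.075983,
   0.071276,
   0.066999
  ],
  [
   0.122894,
   0.109891,
   0.10362,
   0.098367,
   0.08914,
   0.08183,
   0.077449,
   0.073852,
   0.06836,
   0.063946,
   0.060152
  ],
  [
   0.100586,
   0.089843,
   0.084782,
   0.08031,
   0.072981,
   0.067147,
   0.063387,
   0.060469,
   0.055945,
   0.052391,
   0.049226
  ],
  [
   0.086129,
   0.078745,
   0.074268,
   0.069578,
   0.063575,
   0.058187,
   0.055009,
   0.052597,
   0.048666,
   0.045637,
   0.042968
  ],
  [
   0.07194,
   0.063595,
   0.060278,
   0.056882,
   0.05206,
   0.047929,
   0.045129,
   0.043053,
   0.039925,
   0.037368,
   0.035202
  ],
  [
   0.060287,
   0.054635,
   0.052378,
   0.049363,
   0.04497,
   0.041171,
   0.03899,
   0.037259,
   0.034437,
   0.032375,
   0.030492
  ],
  [
   0.054613,
   0.049633,
   0.047249,
   0.044122,
   0.040436,
   0.037159,
   0.035031,
   0.033388,
   0.030948,
   0.029041,
   0.027309
  ],
  [
   0.046674,
   0.041998,
   0.039711,
   0.037412,
   0.03416,
   0.031388,
   0.029645,
   0.028196,
   0.026236,
   0.024631,
   0.023245
  ],
  [
   0.038261,
   0.035176,
   0.033369,
   0.031414,
   0.028606,
   0.026255,
   0.024759,
   0.023694,
   0.021987,
   0.020603,
   0.019407
  ],
  [
   0.032145,
   0.028835,
   0.027251,
   0.025761,
   0.023395,
   0.021464,
   0.02028,
   0.019361,
   0.017937,
   0.016795,
   0.015821
  ],
  [
   0.02771,
   0.024697,
   0.023478,
   0.022171,
   0.020259,
   0.018624,
   0.017581,
   0.016795,
   0.01557,
   0.014623,
   0.013775
  ]
 ]
}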