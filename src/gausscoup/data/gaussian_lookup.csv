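# Monte-Carlo Gaussian values of amplitude/log envelope correlations.
# Generated by scripts/build_lookup_tables.py --seed 12345 --n 1000000 --grid 100
# Column 1: |c| for pec_* rows interpretation; |lagged coherence| for opec_*/lopec_* columns.
predictor,pec_amplitude,pec_log,opec_amplitude,opec_log,lopec_power,lopec_amplitude,lopec_log
0.000000,0.000297,-0.000243,-0.000409,0.000003,-0.000356,-0.000389,-0.000552
0.010000,-0.001517,-0.001308,-0.000126,-0.001219,-0.000050,-0.001197,-0.002516
0.020000,-0.000529,-0.000486,-0.000371,-0.000744,0.000436,0.000087,-0.000247
0.030000,0.000201,-0.000044,-0.000425,0.000815,0.000502,0.000140,-0.000335
0.040000,0.001560,0.001877,0.000260,-0.000206,0.002067,0.001458,-0.000505
0.050000,0.002423,0.001711,0.001912,0.000647,0.003219,0.002740,0.001358
0.060000,0.003530,0.002298,0.004232,0.002391,0.005638,0.005128,0.002817
0.070000,0.004713,0.003398,0.004563,0.002636,0.006833,0.005775,0.002574
0.080000,0.005747,0.004032,0.005647,0.003536,0.008937,0.007388,0.003902
0.090000,0.006698,0.003786,0.007668,0.004734,0.009271,0.008885,0.005369
0.100000,0.009991,0.006782,0.008378,0.006581,0.013119,0.012396,0.007809
0.110000,0.009895,0.006704,0.012559,0.008452,0.017659,0.016221,0.009419
0.120000,0.014903,0.009741,0.011585,0.007718,0.018732,0.015955,0.007730
0.130000,0.014570,0.009480,0.017235,0.011915,0.024528,0.021406,0.011554
0.140000,0.018943,0.013283,0.018015,0.011901,0.025734,0.023263,0.012307
0.150000,0.019514,0.012960,0.018071,0.012464,0.028121,0.025903,0.014458
0.160000,0.024214,0.016838,0.023841,0.014653,0.037901,0.033019,0.017087
0.170000,0.026159,0.017446,0.025461,0.016961,0.037321,0.034171,0.018879
0.180000,0.029620,0.019924,0.029698,0.019483,0.043649,0.040068,0.023348
0.190000,0.032024,0.021974,0.032620,0.022050,0.048336,0.043641,0.024092
0.200000,0.035806,0.024580,0.035914,0.024127,0.054437,0.049012,0.027477
0.210000,0.041636,0.027342,0.038550,0.025417,0.060136,0.054568,0.029664
0.220000,0.045376,0.030494,0.043855,0.029251,0.064615,0.059185,0.033190
0.230000,0.050906,0.034775,0.049197,0.033719,0.072601,0.066064,0.038035
0.240000,0.052480,0.034949,0.054487,0.036369,0.079005,0.072036,0.040727
0.250000,0.056977,0.037920,0.056916,0.038390,0.083774,0.077097,0.044884
0.260000,0.062117,0.042085,0.062295,0.040677,0.089536,0.081931,0.046048
0.270000,0.067829,0.046334,0.066741,0.044192,0.096280,0.088561,0.050775
0.280000,0.073901,0.049597,0.073498,0.050159,0.104829,0.097266,0.057079
0.290000,0.077275,0.050884,0.077837,0.052628,0.111084,0.101981,0.058635
0.300000,0.082225,0.054974,0.083420,0.055621,0.118931,0.108565,0.062257
0.310000,0.088547,0.060979,0.090336,0.061371,0.126023,0.116346,0.067937
0.320000,0.095120,0.063171,0.095286,0.064207,0.135341,0.124718,0.073414
0.330000,0.102090,0.068875,0.100620,0.067669,0.140464,0.130656,0.076949
0.340000,0.106431,0.072088,0.108075,0.074088,0.149651,0.139066,0.082608
0.350000,0.114152,0.077997,0.112556,0.076587,0.156737,0.145498,0.085979
0.360000,0.117783,0.081212,0.120411,0.081766,0.166594,0.155261,0.092456
0.370000,0.125375,0.085420,0.126908,0.086197,0.174454,0.162869,0.096828
0.380000,0.132490,0.090902,0.131616,0.089914,0.179243,0.168272,0.100596
0.390000,0.139045,0.095278,0.140323,0.095651,0.190852,0.178812,0.107250
0.400000,0.147508,0.101475,0.147818,0.100929,0.200079,0.187182,0.112821
0.410000,0.154643,0.106486,0.156332,0.107366,0.208646,0.196395,0.118291
0.420000,0.163292,0.113978,0.164891,0.114139,0.219105,0.205617,0.124772
0.430000,0.171023,0.119163,0.170422,0.117546,0.224779,0.212185,0.129540
0.440000,0.178566,0.124495,0.178142,0.123677,0.234586,0.222112,0.136729
0.450000,0.189556,0.131278,0.187942,0.129702,0.244660,0.231520,0.142026
0.460000,0.197864,0.137491,0.196693,0.135500,0.255997,0.242243,0.149520
0.470000,0.204733,0.142307,0.205505,0.143468,0.262669,0.250240,0.155494
0.480000,0.214757,0.149834,0.214975,0.149618,0.274918,0.261674,0.163685
0.490000,0.223652,0.155783,0.223659,0.156110,0.285115,0.271431,0.170257
0.500000,0.233817,0.164168,0.233421,0.163722,0.296828,0.282381,0.177662
0.510000,0.242800,0.170684,0.243231,0.170143,0.306774,0.292151,0.184785
0.520000,0.252044,0.177096,0.249578,0.174083,0.313434,0.299283,0.188550
0.530000,0.261413,0.183574,0.261763,0.184103,0.326083,0.311951,0.198601
0.540000,0.272358,0.191997,0.271542,0.192904,0.336028,0.322158,0.206326
0.550000,0.282431,0.200753,0.283396,0.201257,0.349968,0.335519,0.216913
0.560000,0.293218,0.209431,0.291989,0.207215,0.358031,0.343459,0.222211
0.570000,0.304543,0.217655,0.303009,0.215827,0.368447,0.354374,0.230155
0.580000,0.314919,0.224542,0.315369,0.224424,0.382603,0.368068,0.240144
0.590000,0.327366,0.234101,0.325252,0.232110,0.393072,0.378139,0.247511
0.600000,0.338475,0.243433,0.337444,0.241961,0.404102,0.389952,0.257550
0.610000,0.349422,0.251279,0.348813,0.250601,0.415256,0.400898,0.266146
0.620000,0.361192,0.261240,0.360863,0.260802,0.426620,0.412484,0.275159
0.630000,0.372484,0.270758,0.371887,0.269896,0.437448,0.423926,0.284414
0.640000,0.384765,0.279558,0.385759,0.280849,0.450714,0.436959,0.294458
0.650000,0.396516,0.288615,0.397989,0.290869,0.463636,0.448823,0.303892
0.660000,0.410628,0.301148,0.411189,0.301636,0.474706,0.461642,0.314923
0.670000,0.424351,0.312017,0.422861,0.309990,0.487426,0.472692,0.322964
0.680000,0.437133,0.323124,0.438465,0.324640,0.500706,0.486677,0.335757
0.690000,0.451228,0.333921,0.450329,0.332725,0.513227,0.498901,0.344633
0.700000,0.462968,0.345609,0.464457,0.345388,0.526086,0.511391,0.355145
0.710000,0.478164,0.357778,0.479011,0.358266,0.538917,0.525000,0.367457
0.720000,0.491801,0.368476,0.490702,0.368416,0.550471,0.535767,0.376954
0.730000,0.506982,0.382135,0.507521,0.382647,0.565591,0.551546,0.390933
0.740000,0.522165,0.396004,0.521059,0.394358,0.577685,0.563682,0.401316
0.750000,0.536780,0.408564,0.535489,0.407139,0.590482,0.576692,0.412997
0.760000,0.551143,0.420772,0.551574,0.421104,0.606123,0.591433,0.426309
0.770000,0.565082,0.434212,0.566401,0.435038,0.620027,0.605079,0.437882
0.780000,0.582429,0.450378,0.581243,0.449420,0.631700,0.618263,0.452322
0.790000,0.597567,0.464519,0.598386,0.465983,0.647107,0.633800,0.466018
0.800000,0.613847,0.480140,0.613999,0.481098,0.661272,0.647686,0.480963
0.810000,0.630594,0.495671,0.630535,0.496358,0.676530,0.662260,0.494215
0.820000,0.646798,0.512087,0.648269,0.512383,0.692826,0.678410,0.509471
0.830000,0.663914,0.528749,0.664734,0.529381,0.707018,0.692555,0.522939
0.840000,0.681408,0.546827,0.681968,0.547626,0.721657,0.708079,0.540548
0.850000,0.699397,0.565850,0.699311,0.564845,0.737353,0.723416,0.557097
0.860000,0.716664,0.583063,0.716319,0.583120,0.752318,0.738836,0.573383
0.870000,0.734623,0.602410,0.734393,0.602539,0.768216,0.754264,0.590565
0.880000,0.752877,0.622735,0.753601,0.622757,0.785602,0.771620,0.607888
0.890000,0.771546,0.643567,0.771778,0.642869,0.801168,0.787802,0.627049
0.900000,0.790110,0.665234,0.790429,0.664695,0.817272,0.804292,0.645667
0.910000,0.810470,0.689993,0.810470,0.689466,0.834953,0.822377,0.668689
0.920000,0.829098,0.712156,0.829375,0.712216,0.851521,0.839321,0.689319
0.930000,0.849372,0.738542,0.849914,0.739442,0.869478,0.857887,0.714117
0.940000,0.869822,0.765148,0.869717,0.765659,0.886428,0.875932,0.738766
0.950000,0.890563,0.794123,0.890291,0.793402,0.904760,0.894960,0.766425
0.960000,0.911488,0.825554,0.911160,0.825407,0.922856,0.914218,0.797137
0.970000,0.932907,0.858819,0.932580,0.858097,0.941617,0.934465,0.831411
0.980000,0.954798,0.896575,0.954678,0.896432,0.960748,0.955580,0.872697
0.990000,0.977097,0.940265,0.977109,0.940038,0.980231,0.977330,0.922089
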