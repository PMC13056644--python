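drug,pt,a_m,b_m,c_f,d_f,rror_pub,ci_lo_pub,ci_hi_pub,p_pub,p_fdr_pub
CRIZOTINIB,NAUSEA,213,9716,459,13043,0.623,0.528,0.734,1.75E-08,0.000000349
CRIZOTINIB,DIARRHOEA,192,9737,317,13185,0.82,0.684,0.983,0.032,0.106
CRIZOTINIB,DYSPNOEA,142,9787,172,13330,1.124,0.899,1.406,0.304,0.695
CRIZOTINIB,VOMITING,141,9788,330,13172,0.575,0.471,0.702,4.96E-08,0.000000496
CRIZOTINIB,FATIGUE,126,9803,212,13290,0.806,0.645,1.006,0.057,0.162
CRIZOTINIB,DECREASED APPETITE,116,9813,142,13360,1.112,0.869,1.423,0.398,0.695
CRIZOTINIB,OEDEMA PERIPHERAL,115,9814,144,13358,1.087,0.853,1.386,0.5,0.695
CRIZOTINIB,PNEUMONIA,109,9820,140,13362,1.061,0.825,1.364,0.646,0.837
CRIZOTINIB,CONSTIPATION,105,9824,159,13343,0.897,0.700,1.149,0.39,0.695
CRIZOTINIB,PERIPHERAL SWELLING,105,9824,155,13347,0.92,0.717,1.180,0.501,0.695
CRIZOTINIB,ASTHENIA,104,9825,139,13363,1.017,0.787,1.313,0.945,0.999
CRIZOTINIB,OFF LABEL USE,103,9826,130,13372,1.079,0.832,1.399,0.572,0.731
CRIZOTINIB,DIZZINESS,93,9836,126,13376,1.002,0.764,1.313,0.999,0.999
CRIZOTINIB,VISUAL IMPAIRMENT,91,9838,172,13330,0.717,0.555,0.925,0.0106,0.0425
CRIZOTINIB,COUGH,89,9840,108,13394,1.123,0.839,1.504,0.435,0.695
CRIZOTINIB,PLEURAL EFFUSION,84,9845,125,13377,0.914,0.682,1.225,0.548,0.731
CRIZOTINIB,PYREXIA,79,9850,107,13395,1.004,0.737,1.368,0.999,0.999
CRIZOTINIB,MALAISE,74,9855,149,13353,0.673,0.509,0.890,0.00555,0.0277
CRIZOTINIB,RENAL IMPAIRMENT,74,9855,53,13449,1.905,1.338,2.714,0.000353,0.00235
CRIZOTINIB,PRODUCT USE ISSUE,62,9867,75,13427,1.126,0.802,1.579,0.503,0.695
ALECTINIB,DISEASE PROGRESSION,136,6404,145,10709,1.568,1.239,1.986,0.000186,0.00371
ALECTINIB,WEIGHT INCREASED,56,6484,156,10698,0.592,0.436,0.805,0.000822,0.00822
ALECTINIB,BLOOD CREATININE INCREASED,53,6487,48,10806,1.839,1.243,2.721,0.0023,0.0129
ALECTINIB,DRUG INEFFECTIVE,98,6442,107,10747,1.528,1.160,2.013,0.00259,0.0129
ALECTINIB,ANAEMIA,63,6477,154,10700,0.676,0.503,0.907,0.00917,0.0336
ALECTINIB,CONSTIPATION,150,6390,320,10534,0.773,0.635,0.940,0.0101,0.0336
ALECTINIB,PNEUMONIA,80,6460,93,10761,1.433,1.061,1.935,0.0189,0.0508
ALECTINIB,ASTHENIA,101,6439,123,10731,1.368,1.050,1.784,0.0203,0.0508
ALECTINIB,BLOOD BILIRUBIN INCREASED,81,6459,96,10758,1.405,1.044,1.892,0.0249,0.0553
ALECTINIB,BRADYCARDIA,44,6496,47,10807,1.553,1.011,2.385,0.0445,0.0704
ALECTINIB,DIARRHOEA,51,6489,105,10749,0.804,0.578,1.120,0.196,0.267
ALECTINIB,FATIGUE,193,6347,342,10512,0.937,0.785,1.118,0.471,0.566
ALECTINIB,PERIPHERAL SWELLING,60,6480,117,10737,0.849,0.619,1.165,0.31,0.566
ALECTINIB,ARTHRALGIA,50,6490,71,10783,1.17,0.814,1.682,0.397,0.567
ALECTINIB,RASH,89,6451,166,10688,0.888,0.679,1.161,0.382,0.567
ALECTINIB,DYSPNOEA,101,6439,158,10696,1.061,0.822,1.369,0.65,0.742
ALECTINIB,NAUSEA,60,6480,113,10741,0.881,0.639,1.215,0.442,0.695
ALECTINIB,COUGH,55,6485,98,10756,0.931,0.660,1.315,0.686,0.762
ALECTINIB,MYALGIA,88,6452,141,10713,1.036,0.784,1.369,0.805,0.847
ALECTINIB,PAIN,56,6484,97,10757,0.957,0.677,1.352,0.806,0.847
BRIGATINIB,NAUSEA,20,1172,43,1498,0.594,0.348,1.016,0.0572,0.607
BRIGATINIB,METASTASES TO LIVER,13,1179,7,1534,2.416,0.961,6.075,0.0607,0.607
BRIGATINIB,BLOOD CREATINE PHOSPHOKINASE INCREASED,52,1140,55,1486,1.232,0.837,1.815,0.29,0.941
BRIGATINIB,PRODUCT DOSE OMISSION ISSUE,9,1183,16,1525,0.725,0.319,1.647,0.442,0.941
BRIGATINIB,DYSPNOEA,9,1183,15,1526,0.774,0.338,1.775,0.545,0.941
BRIGATINIB,PYREXIA,10,1182,17,1524,0.758,0.346,1.662,0.49,0.941
BRIGATINIB,RENAL IMPAIRMENT,11,1181,13,1528,1.095,0.489,2.452,0.826,0.941
BRIGATINIB,COUGH,11,1181,15,1526,0.948,0.434,2.071,0.893,0.941
BRIGATINIB,RASH,12,1180,23,1518,0.671,0.333,1.354,0.266,0.941
BRIGATINIB,PLEURAL EFFUSION,14,1178,17,1524,1.065,0.523,2.170,0.861,0.941
BRIGATINIB,DECREASED APPETITE,15,1177,15,1526,1.297,0.631,2.663,0.479,0.941
BRIGATINIB,AMYLASE INCREASED,15,1177,18,1523,1.078,0.541,2.149,0.83,0.941
BRIGATINIB,DRUG INEFFECTIVE,16,1176,24,1517,0.86,0.455,1.626,0.643,0.941
BRIGATINIB,HYPERTENSION,17,1175,19,1522,1.159,0.600,2.240,0.661,0.941
BRIGATINIB,FATIGUE,18,1174,17,1524,1.374,0.705,2.679,0.35,0.941
BRIGATINIB,METASTASES TO CENTRAL NERVOUS SYSTEM,29,1163,36,1505,1.042,0.635,1.710,0.869,0.941
BRIGATINIB,DIARRHOEA,30,1162,41,1500,0.945,0.586,1.522,0.815,0.941
BRIGATINIB,ALANINE AMINOTRANSFERASE INCREASED,8,1184,6,1535,1.729,0.598,4.996,0.312,0.941
BRIGATINIB,ASPARTATE AMINOTRANSFERASE INCREASED,8,1184,11,1530,0.94,0.377,2.344,0.894,0.941
BRIGATINIB,PULMONARY TOXICITY,11,1181,14,1527,1.016,0.460,2.246,0.969,0.969
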