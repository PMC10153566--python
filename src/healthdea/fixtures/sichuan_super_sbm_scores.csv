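city,2010,2011,2012,2013,2014,2015,2016,2017,2018,Mean
Chengdu,2.930,3.271,3.177,1.614,3.329,3.527,3.707,3.729,3.916,3.244
Zigong,0.805,0.729,0.764,0.191,0.726,0.785,0.789,0.793,0.855,0.715
Panzhihua,0.553,0.551,0.583,0.120,0.633,0.707,0.713,1.002,1.001,0.651
Luzhou,1.018,1.012,1.073,1.034,1.033,0.897,0.871,0.867,1.023,0.981
Deyang,0.833,0.753,0.817,0.257,1.010,1.018,1.047,1.064,1.112,0.879
Mianyang,0.777,0.830,0.823,0.536,0.858,0.928,1.008,1.025,1.011,0.866
Guangyuan,0.797,0.715,0.735,0.145,0.418,0.768,0.765,0.803,0.821,0.663
Suining,0.785,0.889,0.887,1.825,0.847,0.916,0.854,0.874,0.900,0.975
Neijiang,1.012,0.771,0.705,0.230,0.707,0.741,0.794,0.846,0.822,0.736
Leshan,0.786,0.680,0.707,0.189,0.723,0.752,0.752,0.804,0.801,0.688
Nanchong,1.127,1.076,1.033,1.031,1.065,1.053,1.049,1.027,1.034,1.055
Meishan,1.056,1.076,1.027,1.018,1.037,1.026,0.751,0.841,1.018,0.983
Yibin,1.019,0.793,0.712,0.313,0.736,0.788,0.825,0.860,1.001,0.783
Guangan,0.876,0.803,1.015,1.054,0.895,1.013,1.030,1.028,0.861,0.953
Dazhou,0.852,0.852,0.759,1.010,0.781,1.006,1.048,1.059,1.033,0.933
Yaan,1.029,0.749,0.726,0.152,0.661,0.719,0.659,0.728,0.862,0.698
Bazhong,0.899,0.839,0.834,0.230,0.817,1.004,0.901,0.906,0.916,0.816
Ziyang,1.165,1.218,1.212,1.019,1.174,1.172,1.155,1.134,1.120,1.152
Aba,2.107,2.096,2.147,1.000,2.202,2.215,2.166,2.108,2.036,2.009
Mean,1.075,1.037,1.039,0.683,1.034,1.107,1.099,1.131,1.165,1.041
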