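pair,EFFCH,TECHCH,PECH,SECH,TFPCH
2010-2011,0.963,0.933,0.986,0.976,0.899
2011-2012,1.020,0.983,1.005,1.014,1.003
2012-2013,0.950,1.039,0.976,0.974,0.987
2013-2014,1.042,0.843,1.017,1.025,0.878
2014-2015,1.033,0.878,1.041,0.992,0.907
2015-2016,1.020,0.957,0.988,1.033,0.976
2016-2017,1.017,0.983,1.012,1.004,1.000
2017-2018,1.013,0.945,1.013,0.999,0.957
Mean,1.007,0.943,1.005,1.002,0.950
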