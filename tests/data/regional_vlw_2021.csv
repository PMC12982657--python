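location,vlw_overall,share_overall,vlw_t2dm,share_t2dm,vlw_t1dm,share_t1dm
Global,1159179.45,0.76,929240.25,0.61,229939.21,0.15
High SDI,373302.01,0.62,272196.39,0.45,101105.61,0.17
High-middle SDI,353815.96,0.70,307198.12,0.61,46617.84,0.09
Low SDI,22937.20,1.21,18309.78,0.97,4627.42,0.24
Low-middle SDI,210738.12,1.07,171497.58,0.87,39240.54,0.20
Middle SDI,198386.17,0.96,160038.37,0.77,38347.80,0.18
Andean Latin America,5137.95,0.56,4446.51,0.49,691.45,0.08
Australasia,4728.96,0.27,2497.72,0.14,2231.24,0.13
Caribbean,9396.46,1.56,7596.78,1.26,1799.67,0.30
Central Asia,12757.04,0.86,9200.85,0.62,3556.19,0.24
Central Europe,14616.40,0.35,9522.84,0.23,5093.56,0.12
Central Latin America,66126.13,1.53,55781.80,1.29,10344.32,0.24
Central Sub-Saharan Africa,6817.22,1.48,5706.59,1.24,1110.62,0.24
East Asia,240296.20,0.83,225492.05,0.78,14804.15,0.05
Eastern Europe,37900.14,0.54,22848.80,0.33,15051.35,0.22
Eastern Sub-Saharan Africa,11683.03,1.00,8499.99,0.73,3183.04,0.27
High-income Asia Pacific,45551.77,0.51,41008.22,0.46,4543.55,0.05
High-income North America,174298.15,0.67,108778.02,0.42,65520.13,0.25
North Africa and Middle East,126349.20,1.12,109090.39,0.96,17258.81,0.15
Oceania,1975.79,3.03,1791.83,2.74,183.95,0.28
South Asia,152968.02,1.09,123768.76,0.88,29199.26,0.22
Southeast Asia,67833.45,0.76,54295.20,0.61,13538.25,0.15
Southern Latin America,7387.72,0.40,5163.44,0.28,2224.28,0.12
Southern Sub-Saharan Africa,11796.20,1.29,9997.74,1.10,1798.45,0.20
Tropical Latin America,31914.67,0.78,22704.79,0.56,9209.88,0.26
Western Europe,108961.58,0.45,83496.44,0.34,25465.14,0.11
Western Sub-Saharan Africa,20683.38,0.92,17551.47,0.78,3131.91,0.14
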