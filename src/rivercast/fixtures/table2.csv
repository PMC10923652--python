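year,week_lo,week_hi,stratum,ad_count,ai_count,total_count,aff_ad,aff_ai,aff_total
2017,1,18,1,17666,2102,19768,132,14,146
2017,19,20,2,21825,3262,25087,255,25,280
2017,21,21,3,23625,6098,29723,129,43,172
2017,22,22,4,9676,4175,13851,123,60,183
2017,23,23,5,6692,4213,10905,80,57,137
2017,24,24,6,4862,3328,8190,59,67,126
2018,1,18,1,17473,2910,20383,207,56,263
2018,19,19,2,20576,4011,24587,197,64,261
2018,20,20,3,12988,3397,16385,168,56,224
2018,21,21,4,15044,5457,20501,208,104,312
2018,22,22,5,5659,2852,8511,79,48,127
2018,23,24,6,12050,5628,17678,162,84,246
2019,1,18,1,13607,2835,16442,268,63,331
2019,19,19,2,14090,4357,18447,212,71,283
2019,20,20,3,4715,4822,9537,115,57,172
2019,21,21,4,3671,2485,6156,105,61,166
2019,22,22,5,3316,1621,4937,66,35,101
2019,23,23,6,4922,1618,6540,82,34,116
2019,24,24,7,7111,2065,9176,105,36,141
2021,1,17,1,3248,607,3855,100,9,109
2021,18,18,2,13396,2439,15835,149,29,178
2021,19,19,3,12219,2779,14998,247,50,297
2021,20,20,4,11593,4422,16015,171,71,242
2021,21,21,5,5093,2728,7821,87,47,134
2021,22,22,6,3798,2529,6327,53,40,93
2021,23,23,7,5102,2574,7676,100,64,164
2021,24,24,8,6527,2937,9464,117,67,184
2021,25,25,9,3701,1541,5242,43,27,70
2022,1,18,1,32634,5353,37987,192,44,236
2022,19,19,2,38627,7978,46605,147,44,191
2022,20,20,3,19711,6370,26081,116,45,161
2022,21,21,4,12299,6123,18422,90,64,154
2022,22,22,5,7514,5432,12946,80,107,187
2022,23,23,6,6949,5360,12309,76,63,139
2022,24,25,7,12036,7351,19387,94,62,156
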