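year,stratum,week_lo,week_hi,lower_ad,lower_ai,lower_total,upriver_ad,upriver_ai,upriver_total,grand_total
2017,1,12,13,22,3,25,34,4,38,63
2017,2,14,15,24,8,32,85,9,94,126
2018,1,12,15,26,3,29,25,9,34,63
2018,2,16,16,22,5,27,52,7,59,86
2018,3,17,18,53,3,56,108,10,118,174
2019,1,12,16,34,20,54,35,9,44,98
2019,2,17,19,40,4,44,46,9,55,99
2021,1,12,16,25,2,27,43,11,54,81
2021,2,17,20,19,7,26,21,7,28,54
2022,1,12,17,28,4,32,97,26,123,155
2022,2,18,20,37,4,41,86,19,105,146
2022,3,21,24,34,2,36,14,9,23,59
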