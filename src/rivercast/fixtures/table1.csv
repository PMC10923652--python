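year,stat_week,month,day,n_drifts,lower_ad,lower_ai,lower_unk,upriver_ad,upriver_ai,upriver_unk,novsi_ad,novsi_ai,sealion_take,total_chinook
2017,12,March,19,17,14,3,0,10,2,0,0,0,,29
2017,13,March,26,17,14,1,0,32,8,0,0,0,,55
2017,14,April,2,17,27,3,0,66,7,0,2,0,,105
2017,15,April,9,14,14,8,0,75,12,0,0,0,,109
2018,12,March,18,15,3,0,0,1,0,0,0,0,,4
2018,13,March,25,17,3,1,0,8,4,0,0,0,,16
2018,14,April,1,15,4,0,0,8,2,0,0,0,,14
2018,15,April,8,16,16,2,0,12,6,0,0,0,,36
2018,16,April,15,16,26,5,0,67,10,0,0,0,,108
2018,17,April,22,16,40,3,0,73,13,0,0,0,,129
2018,18,April,29,12,18,3,0,43,13,0,0,0,,77
2019,12,March,18,15,1,2,0,0,1,0,0,0,,4
2019,13,March,25,15,4,3,0,4,0,0,0,0,,11
2019,14,April,1,15,3,2,0,5,2,0,1,0,,13
2019,15,April,8,15,2,3,0,2,0,0,0,0,,7
2019,16,April,15,15,27,12,0,26,9,0,0,0,,74
2019,17,April,"21, 22",12,7,2,0,24,9,0,0,0,,42
2019,18,April,"28, 29",14,25,5,0,19,3,0,0,0,,52
2019,19,May,"5, 6",14,7,1,0,6,5,0,0,0,,19
2021,12,March,15,15,0,0,0,1,0,0,2.00,0.00,2,3
2021,13,March,22,15,0,0,0,5,1,0,0.83,0.17,1,7
2021,14,March,29,14,3,0,0,5,1,0,3.56,0.44,4,13
2021,15,April,5,16,9,0,0,5,1,0,12.13,0.87,13,28
2021,16,April,"11, 12",17,6,2,0,19,5,0,13.28,3.72,17,49
2021,17,April,"18, 19",16,8,1,0,12,6,0,17.04,5.96,23,50
2021,18,April,"25, 26",15,13,5,0,15,3,0,11.67,3.33,15,51
2021,19,May,"2, 3",15,3,0,0,5,3,0,17.45,6.55,24,35
2021,20,May,"9, 10",15,4,2,0,2,1,0,5.33,2.67,8,17
2022,12,March,14,13,2,0,0,6,1,0,1.78,0.22,2,11
2022,13,March,"21, 22",15,4,0,0,4,1,0,0.89,0.11,1,10
2022,14,March,28,15,4,0,0,11,2,0,15.88,2.12,18,35
2022,15,April,5,11,8,1,0,14,3,0,9.31,1.69,11,37
2022,16,April,11,15,4,0,0,25,7,0,35.44,8.56,44,80
2022,17,April,"18, 19",15,16,3,0,89,14,0,18.07,2.93,21,143
2022,18,April,25,14,9,0,0,29,4,0,19.90,2.10,22,64
2022,19,May,2,15,14,2,0,29,6,0,10.12,1.88,12,63
2022,20,May,9,13,17,2,0,31,7,0,10.11,1.89,12,69
2022,21,May,16,11,17,2,0,7,8,0,2.12,0.88,3,37
2022,22,May,22,7,1,0,0,3,0,0,2.00,0.00,2,6
2022,23,May,"29, 31",8,9,0,0,4,1,0,0.00,0.00,0,14
2022,24,June,9,3,7,0,0,0,0,0,0.00,0.00,0,7
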