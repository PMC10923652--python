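year,n_points,slope,r2,pred_w0,pred_w1,pred_w2,pred_cum,obs_w0,obs_w1,obs_w2,obs_cum,abs_error
2017,3,4458.9,0.84,,,,,,,,,
2017,4,2380.6,0.57,,,,,,,,,
2018,3,180.8,0.32,,,,,,,,,
2018,4,2486.3,0.58,,,,,,,,,
2018,5,3803.0,0.98,18903,16209,,35111,24587,16385,,40972,14.3
2018,6,4483.1,0.97,18885,,,18885,16385,,,16385,15.3
2018,7,4316.6,0.96,,,,,,,,,
2019,3,719.8,0.64,,,,,,,,,
2019,4,-620.7,0.03,,,,,,,,,
2019,5,6390.2,0.95,16627,9096,4075,29797,18447,9537,6156,34140,12.7
2019,6,6827.6,0.98,9645,4280,,13925,9537,6156,,15693,11.3
2019,7,6820.7,0.98,4267,,,4267,4937,,,4937,13.6
2019,8,6754.5,0.97,,,,,,,,,
2021,3,1328.6,0.79,,,,,,,,,
2021,4,4311.5,0.56,,,,,,,,,
2021,5,8658.1,0.97,14777,11458,11432,37666,14998,16015,7821,38834,3.0
2021,6,8721.0,0.98,11536,11510,5,23052,16015,7821,6327,30163,23.6
2021,7,9348.2,0.94,12503,171,,12675,7821,6327,,14148,10.4
2021,8,8814.2,0.90,27,,,27,6327,,,6327,99.6
2021,9,7876.9,0.81,,,,,,,,,
2022,3,308.4,0.91,,,,,,,,,
2022,4,1675.5,0.62,,,,,,,,,
2022,5,7324.6,0.87,52216,19572,14375,86164,46605,26081,18422,91108,5.4
2022,6,6661.9,0.95,18223,13496,17867,49586,26081,18422,12946,57449,13.7
2022,7,6759.0,0.93,14602,19037,,33638,18422,12946,,31368,7.2
2022,8,6745.6,0.92,19507,,,19507,12946,,,12946,50.7
2022,9,6678.2,0.90,,,,,,,,,
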