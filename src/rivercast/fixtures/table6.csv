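year,genstock,category,abundance
2017,02_WCASSP,H,836
2017,02_WCASSP,W,140
2017,03_WCASFA,W,130
2017,04_WILLAM,H,239
2017,04_WILLAM,W,130
2017,06_KLICKR,H,3054
2017,06_KLICKR,W,279
2017,07_DESCSP,H,7096
2017,07_DESCSP,HNC,335
2017,07_DESCSP,W,130
2017,08_JOHNDR,W,499
2017,09_YAKIMA,H,2622
2017,09_YAKIMA,W,2494
2017,10_UCOLSP,H,5506
2017,10_UCOLSP,HNC,561
2017,10_UCOLSP,W,1610
2017,11_TUCANO,HNC,564
2017,12_HELLSC,H,29584
2017,12_HELLSC,HNC,1756
2017,12_HELLSC,W,2413
2017,13_SFSALM,H,3333
2017,13_SFSALM,HNC,1261
2017,13_SFSALM,W,486
2017,15_MFSALM,W,300
2017,16_UPSALM,H,3127
2017,16_UPSALM,HNC,50
2017,16_UPSALM,W,1096
2017,18_UCOLSF,H,8121
2017,18_UCOLSF,HNC,409
2017,18_UCOLSF,W,7089
2017,19_SRFALL,H,157
2017,19_SRFALL,W,143
2017,20_BONPOOLSP,H,12975
2017,20_BONPOOLSP,HNC,888
2017,21_UMATILLASP,H,7696
2017,21_UMATILLASP,HNC,414
2018,01_YOUNGS,H,76
2018,02_WCASSP,H,2126
2018,02_WCASSP,HNC,55
2018,04_WILLAM,H,203
2018,06_KLICKR,H,820
2018,06_KLICKR,W,52
2018,07_DESCSP,H,1915
2018,07_DESCSP,HNC,261
2018,07_DESCSP,W,596
2018,08_JOHNDR,W,567
2018,09_YAKIMA,H,3159
2018,09_YAKIMA,W,2124
2018,10_UCOLSP,H,5167
2018,10_UCOLSP,HNC,1189
2018,10_UCOLSP,W,2582
2018,11_TUCANO,HNC,498
2018,11_TUCANO,W,163
2018,12_HELLSC,H,32047
2018,12_HELLSC,HNC,2285
2018,12_HELLSC,W,5173
2018,13_SFSALM,H,2673
2018,13_SFSALM,HNC,718
2018,13_SFSALM,W,1276
2018,14_CHMBLN,W,225
2018,15_MFSALM,W,644
2018,16_UPSALM,H,7072
2018,16_UPSALM,HNC,329
2018,16_UPSALM,W,632
2018,18_UCOLSF,H,9242
2018,18_UCOLSF,HNC,782
2018,18_UCOLSF,W,2801
2018,19_SRFALL,H,73
2018,19_SRFALL,W,65
2018,20_BONPOOLSP,H,12510
2018,20_BONPOOLSP,HNC,564
2018,21_UMATILLASP,H,6706
2018,21_UMATILLASP,HNC,671
2019,02_WCASSP,H,825
2019,02_WCASSP,HNC,43
2019,04_WILLAM,H,312
2019,06_KLICKR,H,124
2019,07_DESCSP,H,1314
2019,07_DESCSP,HNC,109
2019,07_DESCSP,W,477
2019,08_JOHNDR,W,474
2019,09_YAKIMA,H,775
2019,09_YAKIMA,HNC,42
2019,09_YAKIMA,W,884
2019,10_UCOLSP,H,5510
2019,10_UCOLSP,HNC,2272
2019,10_UCOLSP,W,2513
2019,11_TUCANO,HNC,268
2019,11_TUCANO,W,91
2019,12_HELLSC,H,19024
2019,12_HELLSC,HNC,1596
2019,12_HELLSC,W,4142
2019,13_SFSALM,H,2054
2019,13_SFSALM,HNC,799
2019,13_SFSALM,W,1054
2019,15_MFSALM,W,308
2019,16_UPSALM,H,1724
2019,16_UPSALM,W,880
2019,18_UCOLSF,H,12709
2019,18_UCOLSF,HNC,483
2019,18_UCOLSF,W,2300
2019,19_SRFALL,W,105
2019,20_BONPOOLSP,H,6781
2019,20_BONPOOLSP,HNC,184
2019,21_UMATILLASP,H,281
2019,21_UMATILLASP,HNC,779
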