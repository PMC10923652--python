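year,genstock,vsi_stock,category,count
2017,02_WCASSP,lower,H,26
2017,02_WCASSP,upriver,H,10
2017,04_WILLAM,lower,H,15
2017,04_WILLAM,lower,W,4
2017,04_WILLAM,upriver,H,9
2017,04_WILLAM,upriver,W,3
2017,06_KLICKR,lower,H,1
2017,07_DESCSP,upriver,H,2
2017,07_DESCSP,upriver,W,1
2017,09_YAKIMA,lower,W,2
2017,09_YAKIMA,upriver,H,1
2017,09_YAKIMA,upriver,W,4
2017,10_UCOLSP,lower,H,1
2017,10_UCOLSP,lower,W,2
2017,10_UCOLSP,upriver,H,12
2017,10_UCOLSP,upriver,W,1
2017,11_TUCANO,upriver,HNC,1
2017,12_HELLSC,lower,H,3
2017,12_HELLSC,lower,HNC,2
2017,12_HELLSC,upriver,H,54
2017,12_HELLSC,upriver,HNC,2
2017,12_HELLSC,upriver,W,1
2017,13_SFSALM,upriver,H,1
2017,16_UPSALM,upriver,H,1
2017,20_BONPOOLSP,lower,HNC,1
2017,20_BONPOOLSP,upriver,H,14
2017,21_UMATILLASP,upriver,H,15
2018,02_WCASSP,lower,H,6
2018,02_WCASSP,lower,W,1
2018,02_WCASSP,upriver,H,8
2018,04_WILLAM,lower,H,61
2018,04_WILLAM,lower,W,7
2018,04_WILLAM,upriver,H,16
2018,06_KLICKR,lower,H,2
2018,06_KLICKR,upriver,H,1
2018,07_DESCSP,lower,H,3
2018,07_DESCSP,upriver,H,3
2018,07_DESCSP,upriver,W,3
2018,08_JOHNDR,upriver,W,1
2018,09_YAKIMA,lower,W,1
2018,09_YAKIMA,upriver,H,4
2018,09_YAKIMA,upriver,W,3
2018,10_UCOLSP,lower,H,4
2018,10_UCOLSP,upriver,H,11
2018,10_UCOLSP,upriver,HNC,2
2018,10_UCOLSP,upriver,W,4
2018,11_TUCANO,upriver,HNC,2
2018,12_HELLSC,lower,H,11
2018,12_HELLSC,lower,HNC,1
2018,12_HELLSC,upriver,H,66
2018,12_HELLSC,upriver,HNC,4
2018,12_HELLSC,upriver,W,3
2018,13_SFSALM,lower,W,1
2018,13_SFSALM,upriver,H,2
2018,16_UPSALM,upriver,H,7
2018,20_BONPOOLSP,lower,H,13
2018,20_BONPOOLSP,upriver,H,53
2018,20_BONPOOLSP,upriver,HNC,2
2018,21_UMATILLASP,lower,H,1
2018,21_UMATILLASP,upriver,H,14
2018,21_UMATILLASP,upriver,HNC,2
2019,01_YOUNGS,upriver,H,1
2019,02_WCASSP,lower,H,9
2019,02_WCASSP,upriver,H,2
2019,04_WILLAM,lower,H,48
2019,04_WILLAM,lower,W,19
2019,04_WILLAM,upriver,H,10
2019,04_WILLAM,upriver,W,2
2019,06_KLICKR,lower,H,1
2019,07_DESCSP,upriver,H,3
2019,09_YAKIMA,lower,H,2
2019,09_YAKIMA,upriver,H,9
2019,09_YAKIMA,upriver,W,4
2019,10_UCOLSP,lower,H,5
2019,10_UCOLSP,lower,HNC,1
2019,10_UCOLSP,lower,W,1
2019,10_UCOLSP,upriver,H,7
2019,10_UCOLSP,upriver,W,5
2019,11_TUCANO,lower,W,2
2019,12_HELLSC,lower,H,4
2019,12_HELLSC,lower,W,1
2019,12_HELLSC,upriver,H,29
2019,12_HELLSC,upriver,HNC,3
2019,12_HELLSC,upriver,W,3
2019,13_SFSALM,upriver,H,1
2019,15_MFSALM,upriver,W,1
2019,16_UPSALM,upriver,H,2
2019,20_BONPOOLSP,lower,H,5
2019,20_BONPOOLSP,upriver,H,16
2019,21_UMATILLASP,upriver,H,1
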