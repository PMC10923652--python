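year,stat_week,lower_ad_pct,lower_ad_est,lower_ad_cpue,lower_ai_pct,lower_ai_est,lower_ai_cpue,lower_total_cpue,upriver_ad_pct,upriver_ad_est,upriver_ad_cpue,upriver_ai_pct,upriver_ai_est,upriver_ai_cpue,upriver_total_cpue
2017,12,0.58,14.00,0.82,0.60,3.00,0.18,1.00,0.42,10.00,0.59,0.40,2.00,0.12,0.71
2017,13,0.30,14.00,0.82,0.11,1.00,0.06,0.88,0.70,32.00,1.88,0.89,8.00,0.47,2.35
2017,14,0.29,27.58,1.62,0.30,3.00,0.18,1.80,0.71,67.42,3.97,0.70,7.00,0.41,4.38
2017,15,0.16,14.00,1.00,0.40,8.00,0.57,1.57,0.84,75.00,5.36,0.60,12.00,0.86,6.21
2018,12,0.75,3.00,0.20,0.00,0.00,0.00,0.20,0.25,1.00,0.07,0.00,0.00,0.00,0.07
2018,13,0.27,3.00,0.18,0.20,1.00,0.06,0.24,0.73,8.00,0.47,0.80,4.00,0.24,0.71
2018,14,0.33,4.00,0.27,0.00,0.00,0.00,0.27,0.67,8.00,0.53,1.00,2.00,0.13,0.67
2018,15,0.57,16.00,1.00,0.25,2.00,0.13,1.13,0.43,12.00,0.75,0.75,6.00,0.38,1.13
2018,16,0.28,26.00,1.63,0.33,5.00,0.31,1.94,0.72,67.00,4.19,0.67,10.00,0.63,4.81
2018,17,0.35,40.00,2.50,0.19,3.00,0.19,2.69,0.65,73.00,4.56,0.81,13.00,0.81,5.38
2018,18,0.30,18.00,1.50,0.19,3.00,0.25,1.75,0.70,43.00,3.58,0.81,13.00,1.08,4.67
2019,12,1.00,1.00,0.07,0.67,2.00,0.13,0.20,0.00,0.00,0.00,0.33,1.00,0.07,0.07
2019,13,0.50,4.00,0.27,1.00,3.00,0.20,0.47,0.50,4.00,0.27,0.00,0.00,0.00,0.27
2019,14,0.38,3.38,0.23,0.50,2.00,0.13,0.36,0.63,5.63,0.38,0.50,2.00,0.13,0.51
2019,15,0.50,2.00,0.13,1.00,3.00,0.20,0.33,0.50,2.00,0.13,0.00,0.00,0.00,0.13
2019,16,0.51,27.00,1.80,0.57,12.00,0.80,2.60,0.49,26.00,1.73,0.43,9.00,0.60,2.33
2019,17,0.23,7.00,0.58,0.18,2.00,0.17,0.75,0.77,24.00,2.00,0.82,9.00,0.75,2.75
2019,18,0.57,25.00,1.79,0.63,5.00,0.36,2.14,0.43,19.00,1.36,0.38,3.00,0.21,1.57
2019,19,0.54,7.00,0.50,0.17,1.00,0.07,0.57,0.46,6.00,0.43,0.83,5.00,0.36,0.79
2021,12,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1.00,3.00,0.20,0.00,0.00,0.00,0.20
2021,13,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1.00,5.83,0.39,1.00,1.17,0.08,0.47
2021,14,0.38,4.33,0.31,0.00,0.00,0.00,0.31,0.63,7.22,0.52,1.00,1.44,0.10,0.62
2021,15,0.64,16.80,1.05,0.00,0.00,0.00,1.05,0.36,9.33,0.58,1.00,1.87,0.12,0.70
2021,16,0.24,9.19,0.54,0.29,3.06,0.18,0.72,0.76,29.09,1.71,0.71,7.66,0.45,2.16
2021,17,0.40,14.81,0.93,0.14,1.85,0.12,1.04,0.60,22.22,1.39,0.86,11.11,0.69,2.08
2021,18,0.46,18.42,1.23,0.63,7.08,0.47,1.70,0.54,21.25,1.42,0.38,4.25,0.28,1.70
2021,19,0.38,9.55,0.64,0.00,0.00,0.00,0.64,0.63,15.91,1.06,1.00,9.55,0.64,1.70
2021,20,0.67,7.56,0.50,0.67,3.78,0.25,0.76,0.33,3.78,0.25,0.33,1.89,0.13,0.38
2022,12,0.25,2.44,0.19,0.00,0.00,0.00,0.19,0.75,7.33,0.56,1.00,1.22,0.09,0.66
2022,13,0.50,4.44,0.30,0.00,0.00,0.00,0.30,0.50,4.44,0.30,1.00,1.11,0.07,0.37
2022,14,0.27,8.24,0.55,0.00,0.00,0.00,0.55,0.73,22.65,1.51,1.00,4.12,0.27,1.78
2022,15,0.36,11.38,1.03,0.25,1.42,0.13,1.16,0.64,19.92,1.81,0.75,4.27,0.39,2.20
2022,16,0.14,8.89,0.59,0.00,0.00,0.00,0.59,0.86,55.56,3.70,1.00,15.56,1.04,4.74
2022,17,0.15,18.75,1.25,0.18,3.52,0.23,1.48,0.85,104.32,6.95,0.82,16.41,1.09,8.05
2022,18,0.24,13.71,0.98,0.00,0.00,0.00,0.98,0.76,44.19,3.16,1.00,6.10,0.44,3.59
2022,19,0.33,17.29,1.15,0.25,2.47,0.16,1.32,0.67,35.82,2.39,0.75,7.41,0.49,2.88
2022,20,0.35,20.58,1.58,0.22,2.42,0.19,1.77,0.65,37.53,2.89,0.78,8.47,0.65,3.54
2022,21,0.71,18.50,1.68,0.20,2.18,0.20,1.88,0.29,7.62,0.69,0.80,8.71,0.79,1.48
2022,22,0.25,1.50,0.21,0.00,0.00,0.00,0.21,0.75,4.50,0.64,0.00,0.00,0.00,0.64
2022,23,0.69,9.00,1.13,0.00,0.00,0.00,1.13,0.31,4.00,0.50,1.00,1.00,0.13,0.63
2022,24,1.00,7.00,2.33,0.00,0.00,0.00,2.33,0.00,0.00,0.00,0.00,0.00,0.00,0.00
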