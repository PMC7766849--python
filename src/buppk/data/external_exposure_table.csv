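dose_mg,pred_auc_5,pred_auc_95,pred_auc_mean,obs_auc_mean,auc_ratio_printed,pred_cmax_5,pred_cmax_95,pred_cmax_mean,obs_cmax_mean,cmax_ratio_printed,reference
16,31.56,71.84,54.13,45.64,1.19,6.15,8.27,7.47,6.25,1.20,Jonsson 2018
4,8.54,22.87,15.86,17.84,0.89,1.91,3.54,2.71,2.44,1.11,Jonsson 2018
4,8.54,22.87,15.86,12.52,1.27,1.91,3.54,2.71,1.84,1.47,Harris (healthy 22-42 y)
8,19.11,40.34,29.74,20.22,1.47,2.51,5.27,3.87,3,1.29,Harris (healthy 22-42 y)
16,31.56,71.84,54.13,34.89,1.55,6.15,8.27,7.47,5.95,1.26,Harris (healthy 22-42 y)
16,31.56,71.84,54.13,32.63,1.66,6.15,8.27,7.47,5.47,1.37,Harris (healthy 22-42 y)
2,,,,,,0.89,1.72,1.12,1.06,1.06,McAleer (opioid-naive 19-42 y)
8,19.11,40.34,29.74,31.81,0.93,2.51,5.27,3.87,4,0.97,McAleer (opioid-naive 19-42 y)
12,29.63,54.22,42.59,41.61,1.02,4.29,7.61,5.84,5.4,1.08,McAleer (opioid-naive 19-42 y)
16,31.56,71.84,54.13,52,1.04,6.15,8.27,7.47,6.4,1.17,McAleer (opioid-naive 19-42 y)
8,19.11,40.34,29.74,24.55,1.21,2.51,5.27,3.87,3.2,1.21,McAleer (opioid-naive 19-42 y)
8,19.11,40.34,29.74,24.6,1.21,2.51,5.27,3.87,3.2,1.21,McAleer (opioid-naive 19-42 y)
4,8.54,22.87,15.86,9.37,1.69,1.91,3.54,2.71,2,1.36,Ciraulo (healthy 21-45 y)
8,19.11,40.34,29.74,19.92,1.49,2.51,5.27,3.87,2.65,1.46,Ciraulo (healthy 21-45 y)
16,31.56,71.84,54.13,34.94,1.55,6.15,8.27,7.47,4.42,1.69,Ciraulo (healthy 21-45 y)
24,51.93,82.74,67.56,48.81,1.38,7.95,10.67,9.44,5.41,1.74,Ciraulo (healthy 21-45 y)
4,8.54,22.87,15.86,13.09,1.21,1.91,3.54,2.71,2.33,1.16,Ciraulo (healthy 21-55 y)
8,19.11,40.34,29.74,23.23,1.28,2.51,5.27,3.87,3.53,1.10,Ciraulo (healthy 21-55 y)
16,31.56,71.84,54.13,39.38,1.37,6.15,8.27,7.47,5.83,1.28,Ciraulo (healthy 21-55 y)
24,51.93,82.74,67.56,47.55,1.42,7.95,10.67,9.44,6.44,1.47,Ciraulo (healthy 21-55 y)
16,31.56,71.84,54.13,54.7,0.99,6.15,8.27,7.47,6.88,1.09,Compton (opioid-dependent 18-65 y)
24,51.93,82.74,67.56,81.1,0.83,7.95,10.67,9.44,9.1,1.04,Compton (opioid-dependent 18-65 y)
32,68.49,102.37,84.31,103,0.82,12.41,16.29,14.21,13.93,1.02,Compton (opioid-dependent 18-65 y)
2,5.14,9.63,7.41,6.5,1.14,0.89,1.72,1.12,0.85,1.32,Greenwald (opioid-dependent 34-45 y)
16,31.56,71.84,54.13,41.9,1.29,6.15,8.27,7.47,5.15,1.45,Moody 2011
16,31.56,71.84,54.13,58.4,0.93,6.15,8.27,7.47,6.97,1.07,Moody 2011
2,5.14,9.63,7.41,10.9,0.68,0.89,1.72,1.12,1.65,0.68,Dong 2019
4,8.54,22.87,15.86,18.1,0.88,1.91,3.54,2.71,2.57,1.05,Dong 2019
8,19.11,40.34,29.74,33.3,0.89,2.51,5.27,3.87,5,0.77,Dong 2019
12,29.63,54.22,42.59,47.7,0.89,4.29,7.61,5.84,7.03,0.83,Dong 2019
16,31.56,71.84,54.13,55.6,0.97,6.15,8.27,7.47,7.84,0.95,Dong 2019
24,51.93,82.74,67.56,73,0.93,7.95,10.67,9.44,11.7,0.81,Dong 2019
4,8.54,22.87,15.86,23.89,0.66,1.91,3.54,2.71,3.31,0.82,Kuhlman 1996
2,5.14,9.63,7.41,6.789,1.09,0.89,1.72,1.12,0.78,1.44,healthy volunteers 18-45 y
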