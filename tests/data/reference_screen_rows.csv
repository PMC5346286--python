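label,a,b,c,total,total_kind,rr_decimals,nnh,risk_ratio,specificity,sensitivity,npv,ppv,ess,ess_print_discrepant
2A ari ed,1381,16094,14367,673793,unexposed,3,17.3,3.706,97.6,8.8,97.9,7.9,6.4,0
2A ari pde5i,2346,15129,26823,673793,unexposed,3,10.6,3.372,97.7,8.0,96.0,13.4,5.8,0
2A ari ll,381,17094,5520,673793,unexposed,3,73.5,2.661,97.5,6.5,99.2,2.2,4.0,0
2A hd ed,915,8448,14367,673793,unexposed,3,13.1,4.583,98.7,6.0,97.9,9.8,4.7,0
2A hd pde5i,1506,7857,26823,673793,unexposed,3,8.3,4.04,98.8,5.3,96.0,16.1,4.1,0
2A hd ll,182,9181,5520,673793,unexposed,3,88.9,2.373,98.6,3.2,99.2,1.9,1.8,0
2A hf ed,628,5919,14367,673793,unexposed,3,13.4,4.499,99.1,4.2,97.9,9.6,3.3,0
2A hf pde5i,1027,5520,26823,673793,unexposed,3,8.5,3.94,99.2,3.7,96.0,15.7,2.8,0
2A hf ll,123,6424,5520,673793,unexposed,3,94.4,2.293,99.0,2.2,99.2,1.9,1.2,0
2A lf ed,383,7036,14367,673793,unexposed,3,33.0,2.421,98.9,2.6,97.9,5.2,1.5,0
2A lf pde5i,707,6712,26823,673793,unexposed,3,18.0,2.394,99.0,2.6,96.0,9.5,1.5,0
2A lf ll,175,7244,5520,673793,unexposed,3,65.0,2.879,98.9,3.1,99.2,2.4,2.0,0
2A du ed,162,1759,14367,673793,unexposed,3,15.9,3.955,99.7,1.1,97.9,8.4,0.9,1
2A du pde5i,280,1641,26823,673793,unexposed,3,9.4,3.661,99.7,1.0,96.0,14.6,0.8,0
2A du ll,37,1884,5520,673793,unexposed,3,90.3,2.351,99.7,0.7,99.2,1.9,0.4,0
2B yl ed,222,5360,2447,321112,unexposed,3,31.1,5.219,98.3,8.3,99.2,4.0,6.7,0
2B yl pde5i,386,5196,3787,321112,unexposed,3,17.4,5.864,98.4,9.2,98.8,6.9,7.6,0
2B yl ll,133,5449,1359,321112,unexposed,3,51.0,5.63,98.3,8.9,99.6,2.4,7.2,0
3Ai prostate_dis,403,4792,296,15634,cohort,1,20.3,2.7,67.9,57.7,97.2,7.8,25.6,0
3Ai enc>27.5,506,7312,193,15634,cohort,1,25.0,2.6,51.0,72.4,97.5,6.5,23.4,0
3Ai encafter>12.5,534,8129,165,15634,cohort,1,26.3,2.6,45.6,76.4,97.6,6.2,22.0,0
3Ai prost_surg,203,1300,496,15634,cohort,1,10.0,3.8,91.3,29.0,96.5,13.5,20.3,0
3Ai days>90.5,497,7685,202,15634,cohort,1,29.7,2.2,48.5,71.1,97.3,6.1,19.6,0
3Ai encprior>8.5,426,6174,273,15634,cohort,1,29.1,2.1,58.7,60.9,97.0,6.5,19.6,0
3Ai nsaid,489,7953,210,15634,cohort,1,34.8,2.0,46.7,70.0,97.1,5.8,16.7,0
3Ai age<=72.6,608,10544,91,15634,cohort,1,29.2,2.7,29.4,87.0,98.0,5.5,16.4,0
3Ai htn,371,5507,328,15634,cohort,1,33.9,1.9,63.1,53.1,96.6,6.3,16.2,0
3Ai depression,162,1591,537,15634,cohort,1,18.6,2.4,89.3,23.2,96.1,9.2,12.5,0
3Ai notes>8.5,343,5470,356,15634,cohort,1,43.9,1.6,63.4,49.1,96.4,5.9,12.4,0
3Ai hdfin,393,6557,306,15634,cohort,1,46.9,1.6,56.1,56.2,96.5,5.7,12.3,0
3Ai notesafter>2.5,473,8346,226,15634,cohort,1,48.8,1.6,44.1,67.7,96.7,5.4,11.8,0
3Ai smoking,284,4561,415,15634,cohort,1,49.6,1.5,69.5,40.6,96.2,5.9,10.1,0
3Ai prost_ca,108,816,591,15634,cohort,1,13.0,2.9,94.5,15.5,96.0,11.7,10.0,0
3Ai androgen,64,229,635,15634,cohort,1,5.6,5.3,98.5,9.2,95.9,21.8,7.6,0
3Ai obesity,104,1140,595,15634,cohort,1,23.7,2.0,92.4,14.9,95.9,8.4,7.2,0
3Ai vascular,260,4500,439,15634,cohort,1,70.2,1.4,69.9,37.2,96.0,5.5,7.1,0
3Ai ssri,147,2106,552,15634,cohort,1,41.7,1.6,85.9,21.0,95.9,6.5,6.9,0
3Ai cyclovir,100,1140,599,15634,cohort,1,25.6,1.9,92.4,14.3,95.8,8.1,6.7,0
3Ai diuretic,210,3818,489,15634,cohort,1,100.0,1.2,74.4,30.0,95.8,5.2,4.5,0
3Ai dutasteride,137,2333,562,15634,cohort,1,78.3,1.3,84.4,19.6,95.7,5.5,4.0,0
3Ai herpes,47,412,652,15634,cohort,1,16.8,2.4,97.2,6.7,95.7,10.2,4.0,0
3Ai diabetes,113,1852,586,15634,cohort,1,68.3,1.3,87.6,16.2,95.7,5.8,3.8,0
3Ai antiandrogen,22,208,677,15634,cohort,1,19.3,2.2,98.6,3.1,95.6,9.6,1.8,0
3Ai peyronie,10,55,689,15634,cohort,1,9.1,3.5,99.6,1.4,95.6,15.4,1.1,0
3Ai hiv,13,145,686,15634,cohort,1,26.3,1.9,99.0,1.9,95.6,8.2,0.9,0
3Aii days>96.5,161,8006,49,15634,cohort,1,76.0,3.0,48.1,76.7,99.3,2.0,24.8,0
3Aii age<=67.4,179,9361,31,15634,cohort,1,73.1,3.7,39.3,85.2,99.5,1.9,24.6,1
3Aii encafter>9.5,170,9532,40,15634,cohort,1,92.8,2.6,38.2,81.0,99.3,1.8,19.1,1
3Aii enc>34.5,133,6871,77,15634,cohort,1,99.3,2.1,55.5,63.3,99.1,1.9,18.8,0
3Aii ssri,68,2185,142,15634,cohort,1,51.1,2.8,85.8,32.4,98.9,3.0,18.2,0
3Aii androgen,39,254,171,15634,cohort,1,8.2,11.9,98.4,18.6,98.9,13.3,16.9,0
3Aii depression,58,1695,152,15634,cohort,1,45.2,3.0,89.0,27.6,98.9,3.3,16.6,0
3Aii nsaid,139,8303,71,15634,cohort,1,151.7,1.7,46.2,66.2,99.0,1.6,12.4,0
3Aii encprior>11.5,98,5677,112,15634,cohort,1,178.3,1.5,63.2,46.7,98.9,1.7,9.9,0
3Aii obesity,34,1210,176,15634,cohort,1,66.2,2.2,92.2,16.2,98.8,2.7,8.3,0
3Aii cyclovir,33,1207,177,15634,cohort,1,69.9,2.2,92.2,15.7,98.8,2.7,7.9,0
3Aii herpes,18,441,192,15634,cohort,1,37.6,3.1,97.1,8.6,98.7,3.9,5.7,0
3Aii alcohol,15,422,195,15634,cohort,1,46.5,2.7,97.3,7.1,98.7,3.4,4.4,0
3Aii peyronie,5,60,205,15634,cohort,1,15.7,5.8,99.6,2.4,98.7,7.7,2.0,0
3B prost_surg,66,120,101,11909,cohort,1,2.9,41.2,99.0,39.5,99.1,35.5,38.5,0
3B prostate_dis,103,3950,64,11909,cohort,1,57.9,3.1,66.4,61.7,99.2,2.5,28.0,0
3B days>179.5,113,5555,54,11909,cohort,1,88.6,2.3,52.7,67.7,99.1,2.0,20.4,0
3B nsaid,121,6173,46,11909,cohort,1,90.6,2.3,47.4,72.5,99.2,1.9,19.9,0
3B htn,94,4392,73,11909,cohort,1,89.9,2.1,62.6,56.3,99.0,2.1,18.9,0
3B age<=71.8,148,8212,19,11909,cohort,1,81.0,3.3,30.1,88.6,99.5,1.8,18.7,0
3B encprior>2.5,128,6842,39,11909,cohort,1,95.5,2.3,41.7,76.6,99.2,1.8,18.4,0
3B ageexp<=70.3,150,8509,17,11909,cohort,1,82.7,3.3,27.5,89.8,99.5,1.7,17.4,0
3B enc>13.5,125,6758,42,11909,cohort,1,102.0,2.2,42.4,74.9,99.2,1.8,17.3,0
3B prost_ca,37,739,130,11909,cohort,1,27.8,4.1,93.7,22.2,98.8,4.8,15.9,0
3B anyhd,114,6400,53,11909,cohort,1,130.3,1.8,45.5,68.3,99.0,1.8,13.8,0
3B hdfin,91,5047,76,11909,cohort,1,154.2,1.6,57.0,54.5,98.9,1.8,11.5,0
3B encafter>3.5,140,8522,27,11909,cohort,1,127.4,1.9,27.4,83.8,99.2,1.6,11.3,0
3B smoking,67,3464,100,11909,cohort,1,142.1,1.6,70.5,40.1,98.8,1.9,10.6,0
3B androgen,20,220,147,11909,cohort,1,14.1,6.6,98.1,12.0,98.7,8.3,10.1,0
3B depression,34,1239,133,11909,cohort,1,70.4,2.1,89.4,20.4,98.7,2.7,9.8,0
3B ssri,39,1618,128,11909,cohort,1,90.5,1.9,86.2,23.4,98.8,2.4,9.6,0
3B dutasteride,40,1902,127,11909,cohort,1,127.3,1.6,83.8,24.0,98.7,2.1,7.8,0
3B vascular,66,3765,101,11909,cohort,1,211.6,1.4,67.9,39.5,98.7,1.7,7.5,0
3B diuretic,55,2998,112,11909,cohort,1,186.3,1.4,74.5,32.9,98.7,1.8,7.4,0
3B diabetes,31,1429,136,11909,cohort,1,121.7,1.6,87.8,18.6,98.7,2.1,6.4,0
3B cyclovir,20,865,147,11909,cohort,1,107.9,1.7,92.6,12.0,98.7,2.3,4.6,0
3B obesity,19,827,148,11909,cohort,1,110.1,1.7,93.0,11.4,98.7,2.2,4.3,0
3B alcohol,10,307,157,11909,cohort,1,55.5,2.3,97.4,6.0,98.6,3.2,3.4,0
3B hiv,7,128,160,11909,cohort,1,26.1,3.8,98.9,4.2,98.6,5.2,3.1,0
3B antiandrogen,7,168,160,11909,cohort,1,37.9,2.9,98.6,4.2,98.6,4.0,2.8,0
3C days>205,30,2557,4,4284,cohort,1,108.2,4.9,39.8,88.2,99.8,1.2,28.1,0
3C cyclovir,12,325,22,4284,cohort,1,33.3,6.4,92.4,35.3,99.4,3.6,27.6,0
3C ssri,13,478,21,4284,cohort,1,47.8,4.8,88.8,38.2,99.4,2.6,27.0,0
3C depression,11,329,23,4284,cohort,1,37.7,5.5,92.3,32.4,99.4,3.2,24.6,0
3C nsaid,16,1181,18,4284,cohort,1,132.7,2.3,72.2,47.1,99.4,1.3,19.3,0
3C smoking,9,582,25,4284,cohort,1,118.2,2.2,86.3,26.5,99.3,1.5,12.8,0
3C htn,7,340,27,4284,cohort,1,75.1,2.9,92.0,20.6,99.3,2.0,12.6,0
3C hiv,4,38,30,4284,cohort,1,11.3,13.5,99.1,11.8,99.3,9.5,10.9,0
3C diabetes,2,39,32,4284,cohort,1,24.2,6.5,99.1,5.9,99.2,4.9,5.0,0
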