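participant_id,age,gender,fix_count_level1,fix_avgdur_level1,fix_sddur_level1,fix_count_level2,fix_avgdur_level2,fix_sddur_level2,fix_count_level3,fix_avgdur_level3,fix_sddur_level3,fix_count_level4,fix_avgdur_level4,fix_sddur_level4,total_time,total_correct
20,9,F,206,172.72,67.03,31,193.10,74.89,74,188.59,68.65,93,188.08,67.93,174.96,15
25,12,M,46,153.85,58.53,29,160.49,70.62,22,128.40,37.64,30,142.66,72.09,132.79,15
28,11,M,43,162.42,59.04,11,167.07,57.24,9,121.98,9.82,19,158.42,55.27,167.61,15
43,11,F,112,182.61,50.90,51,167.70,90.66,84,165.43,78.35,21,133.15,39.96,149.63,15
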