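participant_id,age,gender,fix_count_level1,fix_avgdur_level1,fix_sddur_level1,fix_count_level2,fix_avgdur_level2,fix_sddur_level2,fix_count_level3,fix_avgdur_level3,fix_sddur_level3,fix_count_level4,fix_avgdur_level4,fix_sddur_level4,total_time,total_correct
15,11,F,125,169.91,80.86,180,167.95,74.16,209,168.85,71.15,245,167.82,69.23,171.33,9
16,9,F,138,237.16,128.35,35,243.44,94.41,50,240.26,90.68,98,235.15,84.44,189.66,6
29,12,M,91,174.38,76.58,38,185.29,91.79,17,179.01,70.67,36,176.08,70.79,192.56,9
36,8,M,87,163.61,69.03,142,159.41,60.23,164,165.25,71.36,186,167.99,76.02,192.34,8
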