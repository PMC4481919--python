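participant_id,time_level1,correct_level1,time_level2,correct_level2,time_level3,correct_level3,time_level4,correct_level4,total_time,total_correct
12,40.58,4,34.62,4,47.94,2,48.13,3,171.28,13
15,36.79,4,36.83,2,48.66,0,49.03,3,171.33,9
13,34.76,4,48.28,4,48.29,3,48.33,3,179.67,14
14,40.87,4,30.72,4,48.06,2,47.29,3,166.95,13
16,44.99,4,48.77,1,48.35,0,47.53,1,189.66,6
17,47.48,4,48.08,3,48.05,4,48.26,2,191.89,13
18,48.81,3,47.71,3,47.82,2,38.03,2,182.39,10
19,42.01,4,33.93,4,47.95,2,24.86,4,148.77,14
20,43.62,4,40.49,4,47.99,3,42.85,4,174.96,15
21,29.76,3,24.35,4,48.12,2,21.47,4,123.72,13
22,31.21,4,33.36,4,43.60,2,40.81,2,148.98,12
23,48.71,3,33.31,4,48.09,4,46.19,3,176.32,14
24,39.25,4,41.33,4,48.24,1,39.53,2,168.37,11
25,25.63,4,29.38,4,48.03,4,29.73,3,132.79,15
26,30.11,4,48.50,3,48.28,1,39.94,3,166.84,11
27,48.90,3,44.77,4,48.07,2,47.92,3,189.67,12
28,43.09,4,41.57,4,47.94,3,35.00,4,167.61,15
29,48.53,4,48.12,3,47.82,0,48.07,2,192.56,9
30,48.65,4,37.18,0,41.56,4,39.36,4,166.77,12
31,39.92,4,33.26,3,47.76,1,44.94,2,165.91,10
32,48.72,4,46.81,3,48.09,2,48.25,2,191.89,11
33,42.77,4,46.85,4,47.90,2,37.31,3,174.85,13
34,46.62,4,31.48,4,47.93,3,43.86,2,169.92,13
35,48.60,3,48.95,4,48.42,2,48.79,2,194.78,11
36,48.69,3,46.78,3,48.29,1,48.57,1,192.34,8
37,49.08,4,48.84,3,48.52,1,47.88,2,194.34,10
38,35.96,4,46.81,4,46.56,3,48.62,3,177.97,14
39,46.30,4,39.33,3,47.39,1,46.84,2,179.88,10
40,40.34,4,36.38,3,48.07,3,48.20,1,172.99,11
41,38.17,4,45.31,3,48.08,2,39.87,4,171.45,13
42,48.50,4,27.59,4,47.95,2,48.02,2,172.07,12
43,48.03,3,23.81,4,38.89,4,38.89,4,149.63,15
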