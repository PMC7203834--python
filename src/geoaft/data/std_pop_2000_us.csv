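# 2000 U.S. standard million population by 5-year age band (Census P25-1130 /
# SEER 19 age groups). band_end = 999 denotes the open-ended 85+ band.
band_start,band_end,weight
0,4,69135
5,9,72533
10,14,73032
15,19,72169
20,24,66478
25,29,64529
30,34,71044
35,39,80762
40,44,81851
45,49,72118
50,54,62716
55,59,48454
60,64,38793
65,69,34264
70,74,31773
75,79,26999
80,84,17842
85,999,15508
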