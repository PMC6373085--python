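age_band,sex,count
0-4,male,28000
0-4,female,27000
5-9,male,30000
5-9,female,29000
10-14,male,32000
10-14,female,31000
15-19,male,33000
15-19,female,32000
20-24,male,33000
20-24,female,32000
25-29,male,32000
25-29,female,32000
30-34,male,33000
30-34,female,33000
35-39,male,36000
35-39,female,36000
40-44,male,39000
40-44,female,39000
45-49,male,38000
45-49,female,39000
50-54,male,34000
50-54,female,35000
55-59,male,29000
55-59,female,30000
60-64,male,23000
60-64,female,24000
65-69,male,18000
65-69,female,20000
70-74,male,14000
70-74,female,16000
75-79,male,11000
75-79,female,14000
80-84,male,7000
80-84,female,10000
85+,male,4000
85+,female,8000
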