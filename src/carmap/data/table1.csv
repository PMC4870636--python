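age_band,gender,cases,population
18-24,F,6,7651
18-24,M,11,6799
25-39,F,31,15865
25-39,M,86,14859
40-54,F,69,12906
40-54,M,85,11108
55+,F,36,31752
55+,M,34,25953
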