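kind,key,proportion
gender,f,0.506
gender,m,0.494
age,0-9,0.092
age,10-19,0.093
age,20-29,0.108
age,30-39,0.130
age,40-49,0.119
age,50-59,0.153
age,60-69,0.129
age,70-79,0.092
age,80+,0.084
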