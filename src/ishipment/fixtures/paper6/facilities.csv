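facility_id,parallel_lines,capital_cost,fixed_variable_cost,region
m1,4,600000,1200000,UK
m2,31,4650000,9300000,EU
m3,10,1500000,3000000,EU
m4,4,600000,1200000,EU
m5,31,4650000,9300000,US
m6,10,1500000,3000000,UK
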