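facility_id,parallel_lines,capital_cost,fixed_variable_cost,region
f1,2,8000,16000,north
f2,3,9000,21000,south
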