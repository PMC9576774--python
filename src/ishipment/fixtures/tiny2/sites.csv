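site_id,hospital_id,daily_capacity
s1,g1,8
s2,g2,8
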