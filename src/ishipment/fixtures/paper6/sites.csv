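site_id,hospital_id,daily_capacity
c1,h1,8
c2,h2,8
c3,h3,8
c4,h4,8
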