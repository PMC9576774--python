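mode_id,duration_days
e1,1
e2,2
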