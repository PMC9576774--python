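mode_id,duration_days
courier24,1
courier48,2
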