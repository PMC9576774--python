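key,value
TLS,1
TMFE,7
TQC,7
CQC,15000
CVM,25000
HORIZON,122
FMIN,0
FMAX,1
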