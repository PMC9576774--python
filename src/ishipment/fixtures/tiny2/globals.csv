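key,value
TLS,1
TMFE,3
TQC,2
CQC,500
CVM,1000
HORIZON,30
FMIN,0
FMAX,1
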