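site_id,facility_id,mode_id,unit_cost
s1,f1,e1,300
s1,f1,e2,120
s1,f2,e1,500
s1,f2,e2,200
s2,f1,e1,450
s2,f1,e2,180
s2,f2,e1,350
s2,f2,e2,140
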