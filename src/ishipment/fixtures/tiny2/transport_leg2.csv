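facility_id,hospital_id,mode_id,unit_cost
f1,g1,e1,300
f1,g1,e2,120
f1,g2,e1,450
f1,g2,e2,180
f2,g1,e1,500
f2,g1,e2,200
f2,g2,e1,350
f2,g2,e2,140
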