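facility_id,hospital_id,mode_id,unit_cost
m1,h1,courier24,2500
m1,h1,courier48,1000
m2,h1,courier24,3500
m2,h1,courier48,1400
m3,h1,courier24,3500
m3,h1,courier48,1400
m4,h1,courier24,3500
m4,h1,courier48,1400
m5,h1,courier24,6000
m5,h1,courier48,2400
m6,h1,courier24,2500
m6,h1,courier48,1000
m1,h2,courier24,2600
m1,h2,courier48,1100
m2,h2,courier24,3600
m2,h2,courier48,1500
m3,h2,courier24,3600
m3,h2,courier48,1500
m4,h2,courier24,3600
m4,h2,courier48,1500
m5,h2,courier24,6100
m5,h2,courier48,2500
m6,h2,courier24,2600
m6,h2,courier48,1100
m1,h3,courier24,2700
m1,h3,courier48,1200
m2,h3,courier24,3700
m2,h3,courier48,1600
m3,h3,courier24,3700
m3,h3,courier48,1600
m4,h3,courier24,3700
m4,h3,courier48,1600
m5,h3,courier24,6200
m5,h3,courier48,2600
m6,h3,courier24,2700
m6,h3,courier48,1200
m1,h4,courier24,2800
m1,h4,courier48,1300
m2,h4,courier24,3800
m2,h4,courier48,1700
m3,h4,courier24,3800
m3,h4,courier48,1700
m4,h4,courier24,3800
m4,h4,courier48,1700
m5,h4,courier24,6300
m5,h4,courier48,2700
m6,h4,courier24,2800
m6,h4,courier48,1300
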