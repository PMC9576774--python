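site_id,facility_id,mode_id,unit_cost
c1,m1,courier24,2500
c1,m1,courier48,1000
c1,m2,courier24,3500
c1,m2,courier48,1400
c1,m3,courier24,3500
c1,m3,courier48,1400
c1,m4,courier24,3500
c1,m4,courier48,1400
c1,m5,courier24,6000
c1,m5,courier48,2400
c1,m6,courier24,2500
c1,m6,courier48,1000
c2,m1,courier24,2600
c2,m1,courier48,1100
c2,m2,courier24,3600
c2,m2,courier48,1500
c2,m3,courier24,3600
c2,m3,courier48,1500
c2,m4,courier24,3600
c2,m4,courier48,1500
c2,m5,courier24,6100
c2,m5,courier48,2500
c2,m6,courier24,2600
c2,m6,courier48,1100
c3,m1,courier24,2700
c3,m1,courier48,1200
c3,m2,courier24,3700
c3,m2,courier48,1600
c3,m3,courier24,3700
c3,m3,courier48,1600
c3,m4,courier24,3700
c3,m4,courier48,1600
c3,m5,courier24,6200
c3,m5,courier48,2600
c3,m6,courier24,2700
c3,m6,courier48,1200
c4,m1,courier24,2800
c4,m1,courier48,1300
c4,m2,courier24,3800
c4,m2,courier48,1700
c4,m3,courier24,3800
c4,m3,courier48,1700
c4,m4,courier24,3800
c4,m4,courier48,1700
c4,m5,courier24,6300
c4,m5,courier48,2700
c4,m6,courier24,2800
c4,m6,courier48,1300
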