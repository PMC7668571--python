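# Bench test-lung 1 on a circle system, high-pressure setting
pinsp: 25.0
peep: 5.0
rr: 15.0
ie_e: 2.0
r_v: 22.0
c_v: 0.004
r_lung: 12.0
c_lung: 0.040
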