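compound_id,vina_score,inhibition_pct,ic50_uM
8017-6887,-13.0,74.8,
8018-0047,-12.4,79.1,
C645-0112,-11.8,82.4,4.51
C736-0093,-12.5,67.8,
D063-1105,-13.3,78.6,
D122-0034,-13.1,84.1,4.52
D122-0078,-12.8,82.3,4.49
D638-0102,-12.0,93.6,1.48
D280-0447,-12.2,99.3,1.25
E776-0059,-11.8,96.9,0.97
E776-1501,-12.5,61.1,
E859-1320,-13.1,77.6,
F072-0905,-12.4,99.5,1.41
F351-0364,-13.5,71.2,
F366-0225,-13.4,80.1,5.98
F366-0245,-12.6,91.1,3.45
F486-0373,-12.0,71.7,
G373-0280,-11.8,74.8,
G435-0137,-14.0,75.7,
K306-0682,-13.6,84.2,4.53
L100-0151,-13.9,71.3,
L112-0768,-13.3,66.4,
L153-0098,-12.3,78.4,
L227-1012,-12.5,94.8,1.49
L759-0276,-13.8,63.4,
L759-0287,-13.2,89.3,4.11
G544-1316,-12.9,87.5,4.35
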