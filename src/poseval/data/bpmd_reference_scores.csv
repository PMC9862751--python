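ligand,pose,ifd_score,pose_score,pers_score,comp_score_printed
Eticlopride,1,-474.94,1.008,0.336,-0.672
Eticlopride,2,-474.79,0.944,0.477,-1.441
Eticlopride,3,-474.70,1.894,0.723,-1.721
D638-0102,1,-865.42,1.666,0.752,-2.094
D638-0102,2,-867.53,1.551,0.503,-0.964
D638-0102,3,-864.91,2.286,0.409,0.241
D280-0447,1,-855.76,1.834,0.364,0.014
D280-0447,2,-855.46,1.865,0.241,0.660
D280-0447,3,-856.59,1.355,0.000,1.355
F072-0905,1,-856.49,2.107,0.045,2.107
F072-0905,2,-855.12,2.129,0.000,2.129
F072-0905,3,-855.02,1.913,0.373,0.048
L227-1012,1,-867.86,1.835,0.352,0.758
L227-1012,2,-867.30,2.117,0.000,2.117
E776-0059,1,-859.95,2.246,0.527,-0.389
E776-0059,2,-856.17,1.815,0.000,1.815
Crystal-eticlopride,0,,1.211,0.764,-0.609
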