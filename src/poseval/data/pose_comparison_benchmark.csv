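ligand,dg_top,dg_representative,rmsd_pre_post,expected_verdict
D638-0102,-82.45,-90.35,1.50,refined
D280-0447,-70.59,-73.04,0.78,confirmed
L227-1012,-97.84,-118.15,1.60,refined
F072-0950,-81.32,-91.97,2.18,refined
E776-0059,-98.90,-99.42,3.33,ambiguous
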