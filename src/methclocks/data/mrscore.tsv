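#name=MRscore
#intercept=0
#transform=identity
cg01612140	-0.38253
cg05575921	-0.92224
cg06126421	-1.70129
cg08362785	2.71749
cg10321156	-0.02073
cg14975410	-0.04156
cg19572487	-0.28069
cg23665802	-0.89440
cg24704287	-2.98637
cg25983901	-1.80325
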