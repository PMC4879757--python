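gene	class	consensus
Arg1	M(IL4)	1
Chi3l3	M(IL4)	1
Mrc1	M(IL4)	1
Socs2	M(IL4)	1
Tgm2	M(IL4)	0
Il1rn	M(IL4)	0
Msr1	M(IL4)	0
Il1b	M(LPS,IFNγ)	1
Tnf	M(LPS,IFNγ)	1
Irf5	M(LPS,IFNγ)	1
Nfkbiz	M(LPS,IFNγ)	1
Cd86	M(LPS,IFNγ)	1
Il4ra	M(IL10)	1
Nfil3	M(IL10)	1
Sbno2	M(IL10)	1
Socs3	M(IL10)	1
Fcgr1	M(IL10)	0
Fcgr2b	M(IL10)	0
Fcgr3	M(IL10)	0
Cxcl3	M(IC)	1
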