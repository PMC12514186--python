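gene_id	datasets	tail_phenotype
Crispld1	SHR,MY,TP	False
Cyp26a1		True
Fgfr3	TP	True
Hoxc13		True
Ihh	JH,MY,TP	True
Lmcd1	JH,MY,TP	False
Nkx3-2		True
Nlgn3	JH,MY,TP	False
Npr3	SHR,JH,MY,TP	True
Pappa2	JH	True
Phex	MY	True
Prickle1	JH	True
Ror2		True
Sox5	SHR	True
Sox9		True
Thra	JH	True
Ttll9	JH,MY,TP	False
Twsg1		True
Wnt4	SHR,MY,TP	False
Zim1	JH,MY,TP	False
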