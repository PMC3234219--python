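variant_id	position	ref	alt	cohort	n_het	n_hom_minor
rs9958947	-1495	T	C	HHDL	44	5
rs9958947	-1495	T	C	LHDL	55	9
rs4245232	-1429	C	A	HHDL	44	5
rs4245232	-1429	C	A	LHDL	55	9
rs3829632	-1309	A	G	HHDL	44	5
rs3829632	-1309	A	G	LHDL	55	9
-1358insT	-1358	T	TT	HHDL	17	1
-1358insT	-1358	T	TT	LHDL	23	0
rs34474737	229	T	G	HHDL	96	25
rs34474737	229	T	G	LHDL	103	16
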