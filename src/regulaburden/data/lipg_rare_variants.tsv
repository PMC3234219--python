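variant_id	position	ref	alt	cohort	n_het	n_hom_minor
-1487A>G	-1487	A	G	HHDL	2	0
-1487A>G	-1487	A	G	LHDL	0	0
-1324C>T	-1324	C	T	HHDL	1	0
-1324C>T	-1324	C	T	LHDL	0	0
-1234C>T	-1234	C	T	HHDL	1	0
-1234C>T	-1234	C	T	LHDL	0	0
-1080G>T	-1080	G	T	HHDL	3	0
-1080G>T	-1080	G	T	LHDL	0	0
-612C>A	-612	C	A	HHDL	1	0
-612C>A	-612	C	A	LHDL	0	0
-537T>C	-537	T	C	HHDL	1	0
-537T>C	-537	T	C	LHDL	0	0
-410C>G	-410	C	G	HHDL	1	0
-410C>G	-410	C	G	LHDL	0	0
-403C>G	-403	C	G	HHDL	2	0
-403C>G	-403	C	G	LHDL	0	0
-274C>T	-274	C	T	HHDL	2	0
-274C>T	-274	C	T	LHDL	0	0
-19A>G	-19	A	G	HHDL	1	0
-19A>G	-19	A	G	LHDL	0	0
-1666G>C	-1666	G	C	HHDL	0	0
-1666G>C	-1666	G	C	LHDL	2	0
-1223A>G	-1223	A	G	HHDL	0	0
-1223A>G	-1223	A	G	LHDL	1	0
-1052C>A	-1052	C	A	HHDL	0	0
-1052C>A	-1052	C	A	LHDL	1	0
-175G>A	-175	G	A	HHDL	0	0
-175G>A	-175	G	A	LHDL	1	0
44T>C	44	T	C	HHDL	0	0
44T>C	44	T	C	LHDL	1	0
-324A>G	-324	A	G	HHDL	3	0
-324A>G	-324	A	G	LHDL	1	0
-303A>G	-303	A	G	HHDL	1	0
-303A>G	-303	A	G	LHDL	2	0
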