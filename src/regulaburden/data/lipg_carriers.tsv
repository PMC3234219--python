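individual_id	cohort	variant_id
H001	HHDL	-1487A>G
H001	HHDL	-1080G>T
H002	HHDL	-1234C>T
H002	HHDL	-324A>G
H003	HHDL	-1487A>G
H003	HHDL	-303A>G
H004	HHDL	-1080G>T
H005	HHDL	-1080G>T
H006	HHDL	-1324C>T
H007	HHDL	-612C>A
H008	HHDL	-537T>C
H009	HHDL	-410C>G
H010	HHDL	-403C>G
H011	HHDL	-403C>G
H012	HHDL	-274C>T
H013	HHDL	-274C>T
H014	HHDL	-19A>G
H015	HHDL	-324A>G
H016	HHDL	-324A>G
L001	LHDL	-1666G>C
L002	LHDL	-1666G>C
L003	LHDL	-1223A>G
L004	LHDL	-1052C>A
L005	LHDL	-175G>A
L006	LHDL	44T>C
L007	LHDL	-324A>G
L008	LHDL	-303A>G
L009	LHDL	-303A>G
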