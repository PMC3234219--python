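variant_id	direction	relative_activity	p_value	n_replicates
-1487A>G	decrease	0.55	0.002	6
-1080G>T	decrease	0.60	0.004	6
-537T>C	decrease	0.62	0.008	6
-410C>G	decrease	0.58	0.003	6
-1666G>C	increase	1.65	0.001	6
-1223A>G	increase	1.48	0.006	6
-1052C>A	increase	1.52	0.004	6
-175G>A	increase	1.40	0.009	6
-303A>G	increase	1.45	0.007	6
-1324C>T	null	1.05	0.61	6
-1234C>T	null	0.97	0.72	6
-612C>A	null	1.02	0.85	6
-403C>G	null	0.95	0.44	6
-274C>T	null	1.08	0.37	6
-19A>G	null	0.99	0.91	6
44T>C	null	1.03	0.66	6
-324A>G	null	0.96	0.52	6
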