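# Per-nucleotide physicochemical property registry for CTD descriptors.
# Values are approximate descriptor constants for the free nucleobases
# (heavy-atom graphs for the path-length indices); class columns give the
# ordered low-to-high class partition used by the CTD encoding.
# columns: property	subgroup	A	C	G	U	class_A	class_C	class_G	class_U
hbond_donors	ctd_hbond	1	1	2	1	1	1	2	1
hbond_acceptors	ctd_hbond	3	2	4	2	2	1	3	1
hbond_capacity	ctd_hbond	4	3	6	3	2	1	3	1
hb_basicity	ctd_basicity	0.74	0.86	1.05	0.62	2	2	3	1
hb_acidity	ctd_basicity	0.26	0.29	0.84	0.44	1	1	3	2
polarizability	ctd_basicity	13.1	10.3	13.8	9.8	2	1	3	1
tpsa_base	ctd_tpsa	80.5	67.8	96.2	65.7	2	1	3	1
tpsa_nucleoside	ctd_tpsa	119.3	110.6	135.0	104.6	2	1	3	1
polar_surface_fraction	ctd_tpsa	0.48	0.45	0.56	0.44	2	1	3	1
logp_base	ctd_logp	-0.09	-1.73	-0.96	-1.07	3	1	2	2
logd_phys	ctd_logp	-0.60	-2.10	-1.50	-1.30	3	1	2	2
molar_refractivity	ctd_logp	34.9	26.0	36.2	24.9	2	1	3	1
log_solubility	ctd_solubility	-2.12	-1.15	-3.58	-1.49	2	3	1	3
melting_point	ctd_solubility	633	593	638	608	2	1	3	1
molecular_weight	ctd_solubility	135.1	111.1	151.1	112.1	2	1	3	1
wiener_index	ctd_pathlen	122	58	158	56	3	2	4	1
balaban_index	ctd_pathlen	1.92	2.18	1.77	2.26	2	3	1	4
zagreb_index	ctd_pathlen	54	36	62	34	3	2	4	1
mean_path_length	ctd_pathlen	2.48	2.02	2.71	2.00	2	1	3	1
eccentricity_sum	ctd_pathlen	38	28	44	27	2	1	3	1
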