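region_label	hemisphere	index	region_name
lh_bankssts	L	0	Banks of the superior temporal sulcus (L)
lh_caudalanteriorcingulate	L	1	Caudal anterior cingulate cortex (L)
lh_caudalmiddlefrontal	L	2	Caudal middle frontal gyrus (L)
lh_cuneus	L	3	Cuneus (L)
lh_entorhinal	L	4	Entorhinal cortex (L)
lh_fusiform	L	5	Fusiform gyrus (L)
lh_inferiorparietal	L	6	Inferior parietal cortex (L)
lh_inferiortemporal	L	7	Inferior temporal gyrus (L)
lh_isthmuscingulate	L	8	Isthmus of the cingulate cortex (L)
lh_lateraloccipital	L	9	Lateral occipital cortex (L)
lh_lateralorbitofrontal	L	10	Lateral orbitofrontal cortex (L)
lh_lingual	L	11	Lingual gyrus (L)
lh_medialorbitofrontal	L	12	Medial orbitofrontal cortex (L)
lh_middletemporal	L	13	Middle temporal gyrus (L)
lh_parahippocampal	L	14	Parahippocampal gyrus (L)
lh_paracentral	L	15	Paracentral lobule (L)
lh_parsopercularis	L	16	Pars opercularis (L)
lh_parsorbitalis	L	17	Pars orbitalis (L)
lh_parstriangularis	L	18	Pars triangularis (L)
lh_pericalcarine	L	19	Pericalcarine cortex (L)
lh_postcentral	L	20	Postcentral gyrus (L)
lh_posteriorcingulate	L	21	Posterior cingulate cortex (L)
lh_precentral	L	22	Precentral gyrus (L)
lh_precuneus	L	23	Precuneus (L)
lh_rostralanteriorcingulate	L	24	Rostral anterior cingulate cortex (L)
lh_rostralmiddlefrontal	L	25	Rostral middle frontal gyrus (L)
lh_superiorfrontal	L	26	Superior frontal gyrus (L)
lh_superiorparietal	L	27	Superior parietal cortex (L)
lh_superiortemporal	L	28	Superior temporal gyrus (L)
lh_supramarginal	L	29	Supramarginal gyrus (L)
lh_frontalpole	L	30	Frontal pole (L)
lh_temporalpole	L	31	Temporal pole (L)
lh_transversetemporal	L	32	Transverse temporal cortex (L)
lh_insula	L	33	Insula (L)
rh_bankssts	R	34	Banks of the superior temporal sulcus (R)
rh_caudalanteriorcingulate	R	35	Caudal anterior cingulate cortex (R)
rh_caudalmiddlefrontal	R	36	Caudal middle frontal gyrus (R)
rh_cuneus	R	37	Cuneus (R)
rh_entorhinal	R	38	Entorhinal cortex (R)
rh_fusiform	R	39	Fusiform gyrus (R)
rh_inferiorparietal	R	40	Inferior parietal cortex (R)
rh_inferiortemporal	R	41	Inferior temporal gyrus (R)
rh_isthmuscingulate	R	42	Isthmus of the cingulate cortex (R)
rh_lateraloccipital	R	43	Lateral occipital cortex (R)
rh_lateralorbitofrontal	R	44	Lateral orbitofrontal cortex (R)
rh_lingual	R	45	Lingual gyrus (R)
rh_medialorbitofrontal	R	46	Medial orbitofrontal cortex (R)
rh_middletemporal	R	47	Middle temporal gyrus (R)
rh_parahippocampal	R	48	Parahippocampal gyrus (R)
rh_paracentral	R	49	Paracentral lobule (R)
rh_parsopercularis	R	50	Pars opercularis (R)
rh_parsorbitalis	R	51	Pars orbitalis (R)
rh_parstriangularis	R	52	Pars triangularis (R)
rh_pericalcarine	R	53	Pericalcarine cortex (R)
rh_postcentral	R	54	Postcentral gyrus (R)
rh_posteriorcingulate	R	55	Posterior cingulate cortex (R)
rh_precentral	R	56	Precentral gyrus (R)
rh_precuneus	R	57	Precuneus (R)
rh_rostralanteriorcingulate	R	58	Rostral anterior cingulate cortex (R)
rh_rostralmiddlefrontal	R	59	Rostral middle frontal gyrus (R)
rh_superiorfrontal	R	60	Superior frontal gyrus (R)
rh_superiorparietal	R	61	Superior parietal cortex (R)
rh_superiortemporal	R	62	Superior temporal gyrus (R)
rh_supramarginal	R	63	Supramarginal gyrus (R)
rh_frontalpole	R	64	Frontal pole (R)
rh_temporalpole	R	65	Temporal pole (R)
rh_transversetemporal	R	66	Transverse temporal cortex (R)
rh_insula	R	67	Insula (R)
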