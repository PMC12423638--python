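code	name	lobe	hemisphere
2	Left-Cerebral-White-Matter	WhiteMatter	L
41	Right-Cerebral-White-Matter	WhiteMatter	R
3	Left-Cerebral-Cortex	WhiteMatter	L
42	Right-Cerebral-Cortex	WhiteMatter	R
4	Left-Lateral-Ventricle	Excluded	L
43	Right-Lateral-Ventricle	Excluded	R
5	Left-Inf-Lat-Vent	Excluded	L
44	Right-Inf-Lat-Vent	Excluded	R
14	3rd-Ventricle	Excluded	NA
15	4th-Ventricle	Excluded	NA
72	5th-Ventricle	Excluded	NA
24	CSF	Excluded	NA
16	Brain-Stem	Excluded	NA
7	Left-Cerebellum-White-Matter	Excluded	L
8	Left-Cerebellum-Cortex	Excluded	L
46	Right-Cerebellum-White-Matter	Excluded	R
47	Right-Cerebellum-Cortex	Excluded	R
31	Left-choroid-plexus	Excluded	L
63	Right-choroid-plexus	Excluded	R
77	WM-hypointensities	WhiteMatter	NA
85	Optic-Chiasm	Excluded	NA
10	Left-Thalamus	SubCortical	L
49	Right-Thalamus	SubCortical	R
11	Left-Caudate	SubCortical	L
50	Right-Caudate	SubCortical	R
12	Left-Putamen	SubCortical	L
51	Right-Putamen	SubCortical	R
13	Left-Pallidum	SubCortical	L
52	Right-Pallidum	SubCortical	R
17	Left-Hippocampus	SubCortical	L
53	Right-Hippocampus	SubCortical	R
18	Left-Amygdala	SubCortical	L
54	Right-Amygdala	SubCortical	R
26	Left-Accumbens-area	SubCortical	L
58	Right-Accumbens-area	SubCortical	R
28	Left-VentralDC	SubCortical	L
60	Right-VentralDC	SubCortical	R
1001	ctx-lh-bankssts	Temporal	L
2001	ctx-rh-bankssts	Temporal	R
1002	ctx-lh-caudalanteriorcingulate	Frontal	L
2002	ctx-rh-caudalanteriorcingulate	Frontal	R
1003	ctx-lh-caudalmiddlefrontal	Frontal	L
2003	ctx-rh-caudalmiddlefrontal	Frontal	R
1005	ctx-lh-cuneus	Occipital	L
2005	ctx-rh-cuneus	Occipital	R
1006	ctx-lh-entorhinal	Temporal	L
2006	ctx-rh-entorhinal	Temporal	R
1007	ctx-lh-fusiform	Temporal	L
2007	ctx-rh-fusiform	Temporal	R
1008	ctx-lh-inferiorparietal	Parietal	L
2008	ctx-rh-inferiorparietal	Parietal	R
1009	ctx-lh-inferiortemporal	Temporal	L
2009	ctx-rh-inferiortemporal	Temporal	R
1010	ctx-lh-isthmuscingulate	Parietal	L
2010	ctx-rh-isthmuscingulate	Parietal	R
1011	ctx-lh-lateraloccipital	Occipital	L
2011	ctx-rh-lateraloccipital	Occipital	R
1012	ctx-lh-lateralorbitofrontal	Frontal	L
2012	ctx-rh-lateralorbitofrontal	Frontal	R
1013	ctx-lh-lingual	Occipital	L
2013	ctx-rh-lingual	Occipital	R
1014	ctx-lh-medialorbitofrontal	Frontal	L
2014	ctx-rh-medialorbitofrontal	Frontal	R
1015	ctx-lh-middletemporal	Temporal	L
2015	ctx-rh-middletemporal	Temporal	R
1016	ctx-lh-parahippocampal	Temporal	L
2016	ctx-rh-parahippocampal	Temporal	R
1017	ctx-lh-paracentral	Frontal	L
2017	ctx-rh-paracentral	Frontal	R
1018	ctx-lh-parsopercularis	Frontal	L
2018	ctx-rh-parsopercularis	Frontal	R
1019	ctx-lh-parsorbitalis	Frontal	L
2019	ctx-rh-parsorbitalis	Frontal	R
1020	ctx-lh-parstriangularis	Frontal	L
2020	ctx-rh-parstriangularis	Frontal	R
1021	ctx-lh-pericalcarine	Occipital	L
2021	ctx-rh-pericalcarine	Occipital	R
1022	ctx-lh-postcentral	Parietal	L
2022	ctx-rh-postcentral	Parietal	R
1023	ctx-lh-posteriorcingulate	Parietal	L
2023	ctx-rh-posteriorcingulate	Parietal	R
1024	ctx-lh-precentral	Frontal	L
2024	ctx-rh-precentral	Frontal	R
1025	ctx-lh-precuneus	Parietal	L
2025	ctx-rh-precuneus	Parietal	R
1026	ctx-lh-rostralanteriorcingulate	Frontal	L
2026	ctx-rh-rostralanteriorcingulate	Frontal	R
1027	ctx-lh-rostralmiddlefrontal	Frontal	L
2027	ctx-rh-rostralmiddlefrontal	Frontal	R
1028	ctx-lh-superiorfrontal	Frontal	L
2028	ctx-rh-superiorfrontal	Frontal	R
1029	ctx-lh-superiorparietal	Parietal	L
2029	ctx-rh-superiorparietal	Parietal	R
1030	ctx-lh-superiortemporal	Temporal	L
2030	ctx-rh-superiortemporal	Temporal	R
1031	ctx-lh-supramarginal	Parietal	L
2031	ctx-rh-supramarginal	Parietal	R
1032	ctx-lh-frontalpole	Frontal	L
2032	ctx-rh-frontalpole	Frontal	R
1033	ctx-lh-temporalpole	Temporal	L
2033	ctx-rh-temporalpole	Temporal	R
1034	ctx-lh-transversetemporal	Temporal	L
2034	ctx-rh-transversetemporal	Temporal	R
1035	ctx-lh-insula	Insula	L
2035	ctx-rh-insula	Insula	R
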