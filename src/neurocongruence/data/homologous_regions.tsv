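region	hemisphere	compartment	human_labels	mouse_labels	human_beta	mouse_beta	human_sig	mouse_sig	expression_available
Agranular insula	left	cortical	AVI;AAIC;MI	Agranular insular area	0.200	-0.558	1	1	1
Agranular insula	right	cortical	AVI;AAIC;MI	Agranular insular area	0.164	-0.522	1	1	1
Amygdala	left	non_cortical	Amygdala#	Cortical subplate	0.305	0.163	1	1	1
Amygdala	right	non_cortical	Amygdala#	Cortical subplate	0.201	0.151	1	1	1
Anterior cingulate area	left	cortical	A24pr;a24;p24pr;p24;24dd;24dv;p32pr;d32;a32pr;p32;s32	Anterior cingulate area	-0.102	-0.198	1	0	1
Anterior cingulate area	right	cortical	A24pr;a24;p24pr;p24;24dd;24dv;p32pr;d32;a32pr;p32;s32	Anterior cingulate area	-0.113	-0.267	1	1	1
Bed nucleus of stria terminalis	left	non_cortical	Bed nucleus of stria terminalis	Bed nucleus of stria terminalis	0.466	0.918	1	1	1
Bed nucleus of stria terminalis	right	non_cortical	Bed nucleus of stria terminalis	Bed nucleus of stria terminalis	0.360	0.971	1	1	1
Caudoputamen	left	non_cortical	Caudate#;Putamen#	Caudoputamen	0.093	-0.224	0	1	1
Caudoputamen	right	non_cortical	Caudate#;Putamen#	Caudoputamen	0.059	-0.188	0	1	1
Cerebellar cortex	left	non_cortical	Cerebellar cortex#	Cerebellar cortex	0.430	-0.268	1	1	1
Cerebellar cortex	right	non_cortical	Cerebellar cortex#	Cerebellar cortex	0.478	-0.250	1	1	1
Dentate gyrus, molecular layer	left	non_cortical	Dentate gyrus, molecular layer	Dentate gyrus, molecular layer	-0.029	0.247	0	1	1
Dentate gyrus, molecular layer	right	non_cortical	Dentate gyrus, molecular layer	Dentate gyrus, molecular layer	0.041	0.232	0	1	1
CA1	left	non_cortical	CA1	CA1	0.151	0.385	1	1	1
CA1	right	non_cortical	CA1	CA1	0.109	0.377	0	1	1
CA3	left	non_cortical	CA3	CA3	0.004	0.307	0	1	1
CA3	right	non_cortical	CA3	CA3	0.004	0.411	0	1	1
Entorhinal cortex	left	cortical	EC	Entorhinal area	0.470	-0.090	1	0	1
Entorhinal cortex	right	cortical	EC	Entorhinal area	0.567	-0.138	1	0	1
Globus pallidus	left	non_cortical	Globus Pallidus#	Pallidum	0.154	0.112	1	1	1
Globus pallidus	right	non_cortical	Globus Pallidus#	Pallidum	0.138	0.180	1	1	1
Hippocampus	left	non_cortical	Hippocampus#	Hippocampal region	0.120	0.353	1	1	1
Hippocampus	right	non_cortical	Hippocampus#	Hippocampal region	0.129	0.379	1	1	1
Hypothalamus	left	non_cortical	Hypothalamus	Hypothalamus	0.631	0.185	1	1	1
Hypothalamus	right	non_cortical	Hypothalamus	Hypothalamus	0.617	0.109	1	1	1
Medial amygdalar nucleus	left	non_cortical	Medial amygdalar nucleus	Medial amygdalar nucleus	0.253	0.906	1	1	0
Medial amygdalar nucleus	right	non_cortical	Medial amygdalar nucleus	Medial amygdalar nucleus	0.183	1.034	1	1	0
Medial preoptic area	left	non_cortical	Medial preoptic area	Medial preoptic area	0.636	0.435	1	1	0
Medial preoptic area	right	non_cortical	Medial preoptic area	Medial preoptic area	0.680	0.367	1	1	0
Nucleus accumbens	left	non_cortical	Nucleus accumbens#	Striatum ventral region	-0.311	-0.005	1	0	1
Nucleus accumbens	right	non_cortical	Nucleus accumbens#	Striatum ventral region	-0.249	0.032	1	0	1
Perirhinal area	left	cortical	PeEc;TF;PHA2;PHA3	Perirhinal area	0.033	-0.120	0	0	1
Perirhinal area	right	cortical	PeEc;TF;PHA2;PHA3	Perirhinal area	0.086	-0.108	0	0	1
Piriform cortex	left	cortical	Pir	Piriform cortex	0.460	-0.131	0	0	1
Piriform cortex	right	cortical	Pir	Piriform cortex	0.756	-0.151	1	0	1
Posterior parietal association areas	left	cortical	5m;5mv;5L	Posterior parietal association areas	-0.254	0.016	1	0	1
Posterior parietal association areas	right	cortical	5m;5mv;5L	Posterior parietal association areas	-0.263	0.039	1	0	1
Primary auditory area	left	cortical	A1	Primary auditory area	-0.163	-0.256	0	1	1
Primary auditory area	right	cortical	A1	Primary auditory area	-0.182	-0.209	1	1	1
Primary motor area	left	cortical	4	Primary motor area	-0.124	-0.329	0	1	1
Primary motor area	right	cortical	4	Primary motor area	-0.081	-0.357	0	1	1
Primary somatosensory area	left	cortical	1;2;3a;3b	Primary somatosensory area	-0.237	-0.419	1	1	1
Primary somatosensory area	right	cortical	1;2;3a;3b	Primary somatosensory area	-0.219	-0.241	1	1	1
Primary visual area	left	cortical	V1	Primary visual area	0.175	0.029	1	0	1
Primary visual area	right	cortical	V1	Primary visual area	0.199	-0.102	1	0	1
Retrosplenial area	left	cortical	RSC	Retrosplenial area	0.198	0.004	1	0	1
Retrosplenial area	right	cortical	RSC	Retrosplenial area	0.182	0.035	1	0	1
Subiculum	left	non_cortical	PreS	Subiculum	0.182	0.317	1	1	1
Subiculum	right	non_cortical	PreS	Subiculum	-0.031	0.338	0	1	1
Temporal association areas	left	cortical	FFC;PIT;TE1a;TE1p;TE2a;TF;STV;STSvp;STSva	Temporal association areas	0.057	0.085	0	0	1
Temporal association areas	right	cortical	FFC;PIT;TE1a;TE1p;TE2a;TF;STV;STSvp;STSva	Temporal association areas	0.042	-0.004	0	0	1
Thalamus	left	non_cortical	Thalamus#	Thalamus	-0.028	-0.098	0	0	1
Thalamus	right	non_cortical	Thalamus#	Thalamus	-0.060	-0.139	0	1	1
Ventral orbital area	left	cortical	10r;10v	Ventral orbital area	0.083	-0.209	0	1	1
Ventral orbital area	right	cortical	10r;10v	Ventral orbital area	-0.046	-0.171	0	0	1
Brain stem (midline)	midline	non_cortical	Brainstem#	Midbrain;Hindbrain	0.349	0.200	1	1	1
Medulla (midline)	midline	non_cortical	Medulla	Medulla	0.385	0.204	1	1	1
Midbrain (midline)	midline	non_cortical	Midbrain	Midbrain	0.423	0.191	1	1	1
Pons (midline)	midline	non_cortical	Pons	Pons	0.279	0.065	1	0	1
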