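sample	sex	subgroup	phenotypes	hpo_terms	qc_flags
49	M	CNS_only	hydrocephalus	HP:0000238	
79	M	CNS_plus	neural_tube_defect	HP:0045005	
102	M	CNS_plus	hydrocephalus	HP:0000238	
103	M	CNS_plus	hydrocephalus	HP:0000238	
112	F	CNS_plus	hydrocephalus	HP:0000238	
114	M	CNS_only	hydrocephalus	HP:0000238	
116	M	CNS_plus	hydrocephalus	HP:0000238	
155	M	CNS_plus	hydrocephalus	HP:0000238	
186	M	CNS_plus	hydrocephalus	HP:0000238	
190	M	CNS_plus	hydrocephalus	HP:0000238	
211	M	CNS_only	hydrocephalus	HP:0000238	
222	M	CNS_only	hydrocephalus	HP:0000238	
234	M	CNS_only	hydrocephalus	HP:0000238	
238	M	CNS_only	hydrocephalus	HP:0000238	
240	M	CNS_plus	hydrocephalus	HP:0000238	
244	M	CNS_only	neural_tube_defect	HP:0045005	
246	M	CNS_only	hydrocephalus	HP:0000238	
273	M	CNS_only	hydrocephalus	HP:0000238	
348	M	CNS_only	hydrocephalus	HP:0000238	
350	M	CNS_plus	hydrocephalus	HP:0000238	
351	M	CNS_plus	hydrocephalus	HP:0000238	
357	M	CNS_only	hydrocephalus	HP:0000238	
422	M	CNS_only	neural_tube_defect	HP:0045005	
431	M	CNS_only	hydrocephalus	HP:0000238	
432	M	CNS_only	hydrocephalus	HP:0000238	
438	M	CNS_plus	hydrocephalus	HP:0000238	
456	M	CNS_only	hydrocephalus	HP:0000238	
464	F	CNS_only	hydrocephalus	HP:0000238	
470	M	CNS_only	hydrocephalus	HP:0000238	
479	M	CNS_plus	hydrocephalus	HP:0000238	
482	M	CNS_plus	hydrocephalus	HP:0000238	
532	M	CNS_only	hydrocephalus	HP:0000238	
558	M	CNS_plus	hydrocephalus	HP:0000238	
627	M	CNS_plus	hydrocephalus	HP:0000238	
648	M	CNS_plus	hydrocephalus	HP:0000238	
653	M	CNS_only	hydrocephalus	HP:0000238	
664	M	CNS_only	hydrocephalus	HP:0000238	
730	M	CNS_plus	aplasia_corpus_callosum	HP:0001274	
733	M	CNS_plus	holoprosencephaly	HP:0001360	
747	M	CNS_plus	cerebellar_hypoplasia	HP:0001321	
772	F	CNS_plus	dandy_walker	HP:0001305	
796	M	CNS_only	intracranial_cyst	HP:0030724	
810	M	CNS_only	microcephaly	HP:0000252	
827	M	CNS_plus	destructive_lesion	HP:0100309	
836	M	CNS_plus	abnormal_echo	HP:0002500	
864	M	CNS_only	ventriculomegaly	HP:0002119	
871	M	CNS_plus	aplasia_corpus_callosum	HP:0001274	
882	M	CNS_plus	holoprosencephaly	HP:0001360	
884	M	CNS_only	cerebellar_hypoplasia	HP:0001321	
901	M	CNS_plus	dandy_walker	HP:0001305	
903	F	CNS_plus	intracranial_cyst	HP:0030724	
924	F	CNS_plus	microcephaly	HP:0000252	
931	M	CNS_only	destructive_lesion	HP:0100309	
938	M	CNS_only	abnormal_echo	HP:0002500	
954	M	CNS_only	ventriculomegaly	HP:0002119	
993	F	CNS_plus	aplasia_corpus_callosum	HP:0001274	
1004	M	CNS_only	holoprosencephaly	HP:0001360	
1008	M	CNS_plus	cerebellar_hypoplasia	HP:0001321	
1142	M	CNS_plus	dandy_walker	HP:0001305	
1278	M	CNS_plus	neural_tube_defect	HP:0045005	
1506	M	CNS_plus	microcephaly	HP:0000252	
2942	M	CNS_plus	destructive_lesion	HP:0100309	
U001	M	CNS_plus	abnormal_echo	HP:0002500	cnv_calling_failed
U002	M	CNS_plus	ventriculomegaly	HP:0002119	cnv_calling_failed
U003	M	CNS_plus	aplasia_corpus_callosum	HP:0001274	cnv_calling_failed
U004	M	CNS_plus	holoprosencephaly	HP:0001360	small_cnv_qc_failed
U005	M	CNS_plus	cerebellar_hypoplasia	HP:0001321	small_cnv_qc_failed
U006	M	CNS_plus	dandy_walker	HP:0001305	small_cnv_qc_failed
U007	M	CNS_plus	intracranial_cyst	HP:0030724	small_cnv_qc_failed
U008	M	CNS_plus	microcephaly	HP:0000252	possible_mosaic_47XXY
U009	M	CNS_plus	destructive_lesion	HP:0100309	
U010	M	CNS_plus	abnormal_echo	HP:0002500	
U011	M	CNS_plus	ventriculomegaly	HP:0002119	
U012	M	CNS_plus	aplasia_corpus_callosum	HP:0001274	
U013	M	CNS_plus	holoprosencephaly	HP:0001360	
U014	M	CNS_plus	cerebellar_hypoplasia	HP:0001321	
U015	M	CNS_only	dandy_walker	HP:0001305	
U016	M	CNS_only	intracranial_cyst	HP:0030724	
U017	M	CNS_only	microcephaly	HP:0000252	
U018	M	CNS_only	destructive_lesion	HP:0100309	
U019	M	CNS_only	abnormal_echo	HP:0002500	
U020	M	CNS_only	ventriculomegaly	HP:0002119	
U021	M	CNS_only	aplasia_corpus_callosum	HP:0001274	
U022	M	CNS_only	holoprosencephaly	HP:0001360	
U023	M	CNS_only	cerebellar_hypoplasia	HP:0001321	
U024	M	CNS_only	dandy_walker	HP:0001305	
U025	M	CNS_only	intracranial_cyst	HP:0030724	
U026	F	CNS_only	microcephaly	HP:0000252	
U027	F	CNS_only	destructive_lesion	HP:0100309	
U028	F	CNS_only	abnormal_echo	HP:0002500	
U029	F	CNS_only	ventriculomegaly	HP:0002119	
U030	F	CNS_only	aplasia_corpus_callosum	HP:0001274	
U031	F	CNS_only	holoprosencephaly	HP:0001360	
U032	F	CNS_only	cerebellar_hypoplasia	HP:0001321	
U033	F	CNS_only	dandy_walker	HP:0001305	
U034	F	CNS_only	intracranial_cyst	HP:0030724	
U035	F	CNS_only	microcephaly	HP:0000252	
U036	F	CNS_only	destructive_lesion	HP:0100309	
U037	F	CNS_only	abnormal_echo	HP:0002500	
U038	F	CNS_only	ventriculomegaly	HP:0002119	
U039	F	CNS_only	aplasia_corpus_callosum	HP:0001274	
U040	F	CNS_only	holoprosencephaly	HP:0001360	
U041	F	CNS_only	cerebellar_hypoplasia	HP:0001321	
U042	F	CNS_only	dandy_walker	HP:0001305	
U043	F	CNS_only	intracranial_cyst	HP:0030724	
U044	F	CNS_only	microcephaly	HP:0000252	
U045	F	CNS_only	destructive_lesion	HP:0100309	
U046	F	CNS_only	abnormal_echo	HP:0002500	
U047	F	CNS_only	ventriculomegaly	HP:0002119	
U048	F	CNS_only	aplasia_corpus_callosum	HP:0001274	
U049	F	CNS_only	holoprosencephaly	HP:0001360	
U050	F	CNS_only	cerebellar_hypoplasia	HP:0001321	
U051	F	CNS_only	dandy_walker	HP:0001305	
U052	F	CNS_only	intracranial_cyst	HP:0030724	
U053	F	CNS_only	microcephaly	HP:0000252	
U054	F	CNS_only	destructive_lesion	HP:0100309	
U055	F	CNS_only	abnormal_echo	HP:0002500	
U056	F	CNS_only	ventriculomegaly	HP:0002119	
U057	F	CNS_only	aplasia_corpus_callosum	HP:0001274	
U058	F	CNS_only	holoprosencephaly	HP:0001360	
U059	F	CNS_only	cerebellar_hypoplasia	HP:0001321	
U060	F	CNS_only	dandy_walker	HP:0001305	
U061	F	CNS_only	intracranial_cyst	HP:0030724	
U062	F	CNS_only	microcephaly	HP:0000252	
U063	F	CNS_only	destructive_lesion	HP:0100309	
U064	F	CNS_only	abnormal_echo	HP:0002500	
U065	F	CNS_only	ventriculomegaly	HP:0002119	
U066	F	CNS_only	aplasia_corpus_callosum	HP:0001274	
U067	F	CNS_only	holoprosencephaly	HP:0001360	
U068	F	CNS_only	cerebellar_hypoplasia	HP:0001321	
U069	F	CNS_only	dandy_walker	HP:0001305	
U070	F	CNS_only	intracranial_cyst	HP:0030724	
U071	F	CNS_only	neural_tube_defect	HP:0045005	
U072	F	CNS_only	neural_tube_defect	HP:0045005	
U073	F	CNS_only	neural_tube_defect	HP:0045005	
U074	F	CNS_only	neural_tube_defect	HP:0045005	
U075	F	CNS_only	neural_tube_defect	HP:0045005	
U076	F	CNS_only	neural_tube_defect	HP:0045005	
U077	F	CNS_only	neural_tube_defect	HP:0045005	
U078	F	CNS_only	neural_tube_defect	HP:0045005	
U079	F	CNS_only	neural_tube_defect	HP:0045005	
U080	F	CNS_only	neural_tube_defect	HP:0045005	
U081	F	CNS_only	neural_tube_defect	HP:0045005	
U082	F	CNS_only	neural_tube_defect	HP:0045005	
U083	F	CNS_only	neural_tube_defect	HP:0045005	
U084	F	CNS_only	neural_tube_defect	HP:0045005	
U085	F	CNS_only	neural_tube_defect	HP:0045005	
U086	F	CNS_only	neural_tube_defect	HP:0045005	
U087	F	CNS_only	neural_tube_defect	HP:0045005	
U088	F	CNS_only	neural_tube_defect	HP:0045005	
U089	F	CNS_only	neural_tube_defect	HP:0045005	
U090	F	CNS_only	neural_tube_defect	HP:0045005	
U091	F	CNS_only	neural_tube_defect	HP:0045005	
U092	F	CNS_only	neural_tube_defect	HP:0045005	
U093	F	CNS_only	neural_tube_defect	HP:0045005	
U094	F	CNS_only	neural_tube_defect	HP:0045005	
U095	F	CNS_only	neural_tube_defect	HP:0045005	
U096	F	CNS_only	neural_tube_defect	HP:0045005	
U097	F	CNS_only	neural_tube_defect	HP:0045005	
U098	F	CNS_only	neural_tube_defect	HP:0045005	
U099	F	CNS_only	neural_tube_defect	HP:0045005	
U100	F	CNS_only	neural_tube_defect	HP:0045005	
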