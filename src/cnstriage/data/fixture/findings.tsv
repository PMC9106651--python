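sample	kind	gene	label	tier_class	category	disease	inheritance	size_tier	zygosity
79	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
102	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
240	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
103	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
350	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
482	aneuploidy		+18	P	primary	Trisomy 18		chromosomal	
155	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
351	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
438	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
871	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
747	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
901	aneuploidy		+13	P	primary	Trisomy 13		chromosomal	
827	aneuploidy		+21	P	primary	Trisomy 21		chromosomal	
1008	aneuploidy		+21	P	primary	Trisomy 21		chromosomal	
1142	aneuploidy		+21	P	primary	Trisomy 21		chromosomal	
1506	aneuploidy		+21	P	primary	Trisomy 21		chromosomal	
112	aneuploidy		45,X	P	primary	Turner syndrome		chromosomal	
772	aneuploidy		45,X	P	primary	Turner syndrome		chromosomal	
938	cnv		del(1p36.2p36.3).seq(823534-15632453)x1	P	primary	1p36 deletion syndrome		chromosomal	
864	cnv		dup(2q36.3q37.3).seq(226537458-242997727)x3	P	primary	2q36.3q37.3 duplication		chromosomal	
864	cnv		del(6q26q27).seq(161507517-170879606)x1	P	primary	Terminal 6q deletions		chromosomal	
470	cnv		del(3q12.1q21.2).seq(99540858-125130561)x1	P	primary	3q13.31 deletion syndrome region		chromosomal	
244	cnv		del(4q31.3q32.1).seq(153436540-160087839)x1	P	primary			chromosomal	
186	cnv		dup(5p14.3p15.3).seq(10429-23273021)x3	P	primary			chromosomal	
186	cnv		del(18p11.3p11.3).seq(111935-4272634)x1	P	primary			submicroscopic	
116	cnv		del(6q25.3q27).seq(160630268-170879606)x1	P	primary			chromosomal	
456	cnv		dup(7p22.1).seq(5029498-6809995)x3	P	primary	7p22.1 microduplication syndrome		submicroscopic	
190	cnv		del(7q35q36.3).seq(149299056-159068966)x1	P	primary	Currarino syndrome		chromosomal	
238	cnv		del(7q33q36.3).seq(137529688-159068966)x1	P	primary			chromosomal	
422	cnv		del(7q35q36.1).seq(145049787-159068966)x1	P	primary			chromosomal	
422	cnv		dup(19q13.42q13.43).seq(55330867-59044235)x3	P	primary			submicroscopic	
653	intragenic_cnv	KAT6A	del(8p11.21).seq(41835654-41836946)x1	P	primary	KAT6A exon 6		intragenic	
532	cnv		dup(9p24.1p24.3).seq(10001-6476812)x3	P	primary			chromosomal	
664	cnv		del(13q22.1q34).seq(74369596-115054392)x1	P	primary	13q deletion syndrome		chromosomal	
931	cnv		dup(13q31.2q34).seq(89863557-115054392)x3	P	primary	Partial 13q trisomy		chromosomal	
931	cnv		del(20p13).seq(60001-2226344)x1	P	primary	20p13 microdeletion syndrome		submicroscopic	
796	cnv		del(17p13.2p13.3).seq(1081133-4774754)x1	P	primary	17p13.3 deletion syndrome		submicroscopic	
882	cnv		dup(17p13.3).seq(1150479-1592862)x3	P	primary	17p13.3 microduplication syndrome		submicroscopic	
884	intragenic_cnv	NF1	del(17q11.2).seq(29447084-29503935)x1	P	primary	NF1 microdeletion syndrome, NF1 exon 2-5		intragenic	
954	intragenic_cnv	TM4SF20	del(17q11.2).seq(228230706-228234866)x1	P	primary	TM4SF20 exon 3		intragenic	
810	cnv		del(18p11.2p11.3).seq(111935-15323954)x1	P	primary			chromosomal	
1004	cnv		del(18p11.2p11.3).seq(111935-15334797)x1	P	primary			chromosomal	
49	snv	KAT6B	KAT6B:c.3747delA(p.Gly1251Glufs*21)	P	primary	Genitopatellar syndrome	AD		het
432	snv	STIL	STIL:c.3835C>T(p.Arg1279Cys)	LP	primary	Microcephaly 7, primary	AR		het
432	snv	STIL	STIL:c.2344_2347delTTGC(p.Leu782Thrfs*2)	P	primary	Microcephaly 7, primary	AR		het
211	snv	CC2D2A	CC2D2A:c.3829T>C(p.Cys1277Arg)	LP	primary	Joubert syndrome 9	AR		het
211	snv	CC2D2A	CC2D2A:c.3874G>T(p.Asp1292Tyr)	LP	primary	Joubert syndrome 9	AR		het
234	snv	KAT6B	KAT6B:c.3660dup(p.Arg1221*fs*1)	P	primary	Genitopatellar syndrome	AD		het
246	snv	TUBA1A	TUBA1A:c.748G>T(p.Val250Phe)	LP	primary	Lissencephaly 3	AD		het
273	snv	GJC2	GJC2:c.1125_1135delCGGCCTCCCTG(p.Ala379Glyfs*109)	LP	primary	Lymphatic malformation 3	AD		het
348	snv	DNM1L	DNM1L:c.345_346delAG(p.Glu116Lysfs*6)	LP	primary	Encephalopathy	AD		het
357	snv	FGFR3	FGFR3:c.1948A>G(p.Lys650Glu)	P	primary	Thanatophoric dysplasia	AD		het
431	snv	TUBA1A	TUBA1A:c.614A>T(p.Asp205Val)	LP	primary	Lissencephaly 3	AD		het
464	snv	PDHA1	PDHA1:c.923_929delAGGAAGT(p.Ser312Valfs*1)	LP	primary	Pyruvate dehydrogenase E1-alpha deficiency	XLD		het
479	snv	GLI2	GLI2:c.94dup(p.Ala32Glyfs*34)	LP	primary	Culler-Jones syndrome / Holoprosencephaly 9	AD		het
558	snv	PTPN11	PTPN11:c.1403C>T(p.Thr468Met)	P	primary	Noonan syndrome 1	AD		het
627	snv	NSD1	NSD1:c.5177C>T(p.Pro1726Leu)	LP	primary	Sotos syndrome	AD		het
648	snv	FOXG1	FOXG1:c.171_180delCCCGCCGCCG(p.Pro60Argfs*129)	LP	primary	Rett syndrome, congenital variant	AD		het
730	snv	FANCC	FANCC:c.1330-1G>A	LP	primary	Fanconi anemia, complementation group C	AR		hom
733	snv	SIX3	SIX3:c.339G>A(p.Trp113Stop)	P	primary	Holoprosencephaly 2	AD		het
836	snv	SOX2	SOX2:c.480C>G(p.Tyr160Stop)	P	primary	Optic nerve hypoplasia and abnormalities of CNS	AD		het
903	snv	OFD1	OFD1:c.1103_1106delTGAT(p.Ile369Lysfs*18)	LP	primary	Orofaciodigital syndrome I	XLD		het
924	snv	ARX	ARX:c.1074-1G>A	LP	primary	Lissencephaly	XL		het
2942	snv	NID1	NID1:c.1786C>T(p.Arg596*)	LP	primary	Dandy-Walker malformation	AD		het
993	snv	PDHA1	PDHA1:c.933_936delAAGT(p.Ser312Argfs*13)	P	primary	Pyruvate dehydrogenase E1-alpha deficiency	XLD		het
1278	snv	CC2D2A	CC2D2A:c.4333C>T(p.Arg1445*)	P	primary	Meckel syndrome 6	AR		hom
222	snv	PTCH1	PTCH1:c.2757_2758delCT(p.Phe919Leufs*39)	LP	primary	Basal cell nevus syndrome	AD		het
114	snv	NF1	NF1:c.1742dup(p.Leu581Phefs*6)	P	primary	Neurofibromatosis, type I	AD		het
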