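rsnp_ids	protein	target_genes	function	modification	complex	specific_target
rs2281391	ARID1B	AGAP1,DAXX,HSD17B8,TFDP2,ZBED6,ZC3H11A	HMW	Histone ubiquitination	BAF, nBAF, npBAF, PBAF, SWI/SNF-like_EPAFa, SWI/SNF-like EPAFB, SWI/SNF BRM-BRG1	H2BK120, DNA motif
rs1363175143	CHD4	DAXX,HSD17B8	CR		NuRD
rs1022095596	CLOCK	DAXX,GPC1,HDAC4,HSD17B8,SMG5,ZBED6,ZC3H11A	HMW	Histone acetylation		H3, H4
rs1013929495	CTBP1	AGAP1,DAXX,GPC1,HDAC4,HERC6,HSD17B8,SMG5,TFDP2,ZBED6,ZC3H11A	CR		LSD-CoREST
rs977886453,rs1279727503,rs924734233	DPF2	AGAP1,DAXX,HDAC4,HERC6,HSD17B8,SMG5,TFDP2,ZBED6,ZC3H11A	CR		SWI/SNF BRM-BRG1
rs1465945079	EHMT2	AGAP1,DAXX,HDAC4,ZBED6	HMW	Histone methylation		H3K9
rs777573795	KAT8	ZBED6,ZC3H11A	HMW	Histone acetylation	NSL, CHD8, MLL2/3, COMPASS-like MLL1,2, MLL4/WBP7	H2A, H3, H4
rs1286079777	MGA	AGAP1,DAXX,HDAC4,TFDP2,ZBED6,ZC3H11A	HMW cofactor, TF	Histone methylation, histone acetylation, TF activator, TF repressor	RING2-L3MBTL2, CHD8, MLL2/3, MLL4/WBP7	DNA motif
rs563166047	NCOA2	ZC3H11A	CR cofactor
rs1320061320,rs1395087048	RCOR1	AGAP1,DAXX,GPC1,HDAC4,HERC6,HSD17B8,SMG5,TFDP2	HME cofactor	Histone acetylation	BHC, SCL, LSD-CoREST
rs1346876773	SAP30	DAXX,GPC1,HSD17B8,SMG5,TFDP2,ZBED6,ZC3H11A	HME cofactor	Histone acetylation	mSin3A, mSin3A-like complex
rs930121077,rs907151175	SMARCE1	AGAP1,DAXX,HSD17B8,ZBED6,ZC3H11A,ZC3H11A	CR cofactor		BAF, nBAF, npBAF, PBAF, SWI/SNF_Brg1(I), SWI/SNF_Brg1(II), SWI/SNF_Brm, SWI/SNF-like_EPAFa, WINAC, SWI/SNF-like EPAFB, bBAF
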