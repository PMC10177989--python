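rsnp_ids	gene	function	modification	complex	target	specific_target
rs2281391	ARID1B	HMW	Histone ubiquitination	BAF, nBAF, npBAF, PBAF, SWI/SNF-like_EPAFa, SWI/SNF-like EPAFB, SWI/SNF BRM-BRG1	Histone, DNA	H2BK120, DNA motif
rs536224963	BANP	HMW	Histone acetylation		Histone	H3K9, H4K8
rs3130018	DAXX				Histone	H3.3
rs946554101	HDAC4	HME	Histone acetylation		Histone	H2AKac, H2BKac, H3Kac, H4Kac
rs1053224730	SIRT1	HME, HMW cofactor	Histone acetylation, Histone methylation	eNoSc	Histone	H1K26ac, H3K9ac, H4K16ac
rs1249650489	TRRAP	HMW cofactor	Histone acetylation	SWR, PCAF, TFTC-HAT, NuA4, SAGA, NuA4-related complex, STAGA	Histone
rs958341678	UHRF1	HMR, HMW cofactor	Histone ubiquitination		Histone, DNA	H3K9me3, H3R2, H3, mCG
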