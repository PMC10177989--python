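rsnp_ids	protein	target_genes	printed_n
rs1022095596	CLOCK	ZBED6,HSD17B8,ZC3H11A,SMG5,DAXX,GPC1,HDAC4	7
rs977886453,rs1279727503,rs924734233	DPF2	AGAP1,HERC6,DAXX,ZBED6,ZC3H11A,HSD17B8,HDAC4,TFDP2,SMG5	9
rs1370216229	CUX1	TFDP2,ZBED6,ZC3H11A	3
rs1255551090	BCL11A	HERC6,AGAP1	2
rs995147107	FOSL2	TFDP2,HDAC4,DAXX,AGAP1,HSD17B8,SMG5	6
rs992579579	FOXK2	DAXX,HSD17B8,HDAC4,TFDP2,AGAP1,ZC3H11A,SMG5,ZBED6	8
rs1465639308,rs975045833	IRF1	DAXX,ZC3H11A,HDAC4,TFDP2,HERC6,GPC1,AGAP1,SMG5,ZBED6,HSD17B8	10
rs2570800,rs1402353341	MEF2A	SMG5,HERC6,ZC3H11A,AGAP1,ZBED6,SMG5,HERC6,ZC3H11A,AGAP1,ZBED6	10
rs1286079777	MGA	HDAC4,TFDP2,AGAP1,ZC3H11A,ZBED6,DAXX	6
rs954995579,rs1043408625,rs954995579	NFIB	HERC6,ZBED6,DAXX,HDAC4	4
rs983776002	NFIC	SMG5,DAXX,ZBED6,ZC3H11A,HSD17B8,HERC6,AGAP1,TFDP2,HDAC4	9
rs1484805397	SREBF1	HDAC4,ZBED6,ZC3H11A	3
rs1044184380	TCF12	AGAP1,ZBED6,ZC3H11A,HSD17B8,HDAC4,HERC6,GPC1,SMG5,TFDP2,DAXX	10
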