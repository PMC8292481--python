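chrom	rsid	gene	carrier_maf	fbc_maf	crc_maf	ref_1000g_eur_2014	ref_swedes_249	ref_danes_200	ref_exac_nfe	driver_flag	pub_ratio_crc	pub_ratio_fbc	note
1	rs2297809	CYP4B1	0.25	0.1518	0.1207	0.1302	0.1456	0.12	0.1457	True	2.07	1.65
1	rs4926600	CYP4A22	0.1964	0.1518	0.0641	0.0805	0.0984	NA	0.0868	True	3.06	1.29
2	rs17860405	CASP10	0.1607	0.0893	0.0214	0.0417	0.0382	0.0225	0.0409	True	7.51	1.80
3	rs34492126	DLG1	0.1607	0.0982	0.0684	0.0577	0.0542	0.0575	0.0535	True	2.35	1.64
5	rs2287749	ADAM19	0.2321	0.1518	0.1667	0.1163	0.1426	0.14	0.1350	True	1.39	1.53
6	rs811925	PRDM1	0.375	0.3214	0.1838	0.2048	0.1767	0.1475	0.1758	True	2.04	1.17
9	rs34523498	CDK5RAP2	0.1071	0.0804	0.0256	0.0328	0.0361	0.02	0.0295	True	4.18	1.33
9	rs41305617	NOL8	0.1071	0.0625	0.0219	0.0338	0.0221	NA	0.0302	True	4.89	1.71
11	rs8176786	NELL1	0.125	0.0804	0.0513	0.0547	0.0582	0.06	0.0529	True	2.44	1.55
11	rs117739035	SIGIRR	0.125	0.0804	0.0299	0.0358	0.0482	0.045	0.0347	True	4.18	1.55
12	rs7962217	VWF	0.1071	0.0625	0.0513	0.0507	0.0542	0.0625	0.0545	True	2.09	1.71	healthy-control MAF printed as 0.513; stored as 0.0513, the value consistent with the published ratio 2.09
15	rs35932273	LTK	0.1071	0.0714	0.0256	0.0268	0.0321	0.01	0.0285	True	4.18	1.50
16	rs152451	PALB2	0.125	0.1339	0.0226	0.0934	0.0683	0.0575	0.0955	True	5.53	0.93
20	rs34983477	TP53RK	0.1071	0.0893	0.0513	0.0398	0.0502	0.0275	0.0473	True	2.09	1.20
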