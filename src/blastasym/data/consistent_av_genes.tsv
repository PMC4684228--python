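gene_id	symbol	pole	fold
Xetro.D02339	grip2	vegetal	134.11
Xetro.G00091	nanos1	vegetal	97.32
Xetro.E00365	pat	vegetal	94.4
Xetro.A00019		vegetal	59.12
Xetro.G01160	ddx25	vegetal	37.06
Xetro.H00537	wnt11b	vegetal	25.52
Xetro.A00580	trim36	vegetal	17.74
Xetro.C00749	pcsk6	vegetal	17.4
Xetro.F00403	sulf1	vegetal	15.94
Xetro.N00856	vegt	vegetal	13.52
Xetro.G00335	bicc1	vegetal	12.91
Xetro.A02015	gdf1	vegetal	12.36
Xetro.I00813	mogat1	vegetal	11.13
Xetro.A01360	mov10	vegetal	10.28
Xetro.E01314	otx1	vegetal	10.25
Xetro.K02810	slc12a9	vegetal	9.91
Xetro.F00192	sybu	vegetal	9.87
Xetro.I01736	thoc6	vegetal	7.94
Xetro.A01296	slc25a22	vegetal	7.76
Xetro.J00911	spire1	vegetal	7.74
Xetro.H00830		vegetal	7.42
Xetro.A00833		vegetal	7.22
Xetro.C01112	dnd1	vegetal	7.16
Xetro.F01892	ctdspl	vegetal	7.09
Xetro.A01886	rnf38	vegetal	6.94
Xetro.F00384	rdh10	vegetal	6.64
Xetro.I00127	cnppd1	vegetal	6.16
Xetro.G00368	fgfr2	vegetal	5.88
Xetro.C00709	rhcg	vegetal	5.8
Xetro.B00467	cnksr2	vegetal	5.77
Xetro.K05126	sox7	vegetal	5.71
Xetro.A02337	ppp1r3b	vegetal	5.33
Xetro.B00074	rragc	vegetal	5.26
Xetro.A02205	acsbg2	vegetal	5.06
Xetro.I00550	raph1	vegetal	4.99
Xetro.D02536		vegetal	4.59
Xetro.D01936	plk3	vegetal	4.48
Xetro.F01128	velo1	vegetal	4.33
Xetro.B00910	cldn4	vegetal	4.27
Xetro.H00419		vegetal	4.02
Xetro.A02978	acsl1	vegetal	3.87
Xetro.B01314	rnf41	vegetal	3.85
Xetro.D01271	pbx1	vegetal	3.79
Xetro.D00562	pc.1	vegetal	3.76
Xetro.G00513	sufu	vegetal	3.57
Xetro.B01376	lrp1	vegetal	3.47
Xetro.K00842		vegetal	3.32
Xetro.K02822	znf484	vegetal	3.17
Xetro.K01814		vegetal	2.92
Xetro.D02087		vegetal	2.92
Xetro.B01421		vegetal	2.78
Xetro.H01623	daam1	vegetal	2.75
Xetro.D00538	fam65a	vegetal	2.62
Xetro.D01911	c1orf190	vegetal	2.52
Xetro.E00863	dynlt1	vegetal	2.5
Xetro.K00790		vegetal	2.45
Xetro.D02050	ralgps2	vegetal	2.43
Xetro.A00139	gpbp1	vegetal	2.4
Xetro.A02066	tbc1d1	vegetal	2.4
Xetro.A00748	slc15a4	vegetal	2.28
Xetro.F01187	trak1	vegetal	2.2
Xetro.C01467	pdlim7	vegetal	2.09
Xetro.B00109	eif2c1	vegetal	1.99
Xetro.D02103	kifc3	vegetal	1.93
Xetro.E00664		vegetal	1.88
Xetro.D01799	slc35d1	animal	3.83
Xetro.A01057	smtn	animal	2.83
Xetro.C00309	slc18a2	animal	2.65
Xetro.I00501	nbeal1	animal	2.38
Xetro.B00228	stk40	animal	2.11
Xetro.I01183	nomo3	animal	1.82
Xetro.E01463	bub1	animal	1.75
Xetro.A01908	ptpn9	animal	1.74
Xetro.H00897	rbmx	animal	1.7
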