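# Synthetic insertion catalog: a constructed stand-in for a sequenced 142-clone
# reporter-trap screen across nine common gardens (three sacB GC variants x three
# replicons). Positions and per-event details are simulated; the garden-level
# structure mirrors the screen this package models: 142 clones total, 34 in the
# 88-nt 5'-UTR and 108 in the 1422-nt CDS, with the dominant IS5-family element
# accounting for 71/108 (65.7%) of CDS events.
# coordinates: 1-based, closed intervals, TSS-relative (+1 = first transcribed nt)
garden_id	is_id	position	orientation	tsd_seq	n_clones
L_pA	IS5_1	333	+	TAA	9
L_pA	IS5_1	421	-	TTA	3
L_pA	IS5_1	587	+	ACA	2
L_pA	IS5_1	760	+	TGA	1
L_pA	IS5_1	912	-	TAA	1
L_pA	IS5_1	1103	+	TCA	1
L_pA	IS5_1	1288	-	ATA	1
L_pB	IS5_1	333	+	TAA	5
L_pB	IS5_1	245	-	TTA	2
L_pB	IS5_1	587	+	ACA	2
L_pB	IS5_1	998	+	TGA	1
L_pB	IS5_1	1205	-	TAA	1
L_pB	IS5_1	1402	+	ATA	1
L_Ch	IS5_1	333	+	TAA	4
L_Ch	IS5_1	421	-	TTA	2
L_Ch	IS5_1	760	+	TGA	1
L_Ch	IS5_1	1498	-	ACA	1
M_pA	IS5_1	214	+	TAA	6
M_pA	IS5_1	333	+	TAA	3
M_pA	IS5_1	509	-	TTA	2
M_pA	IS5_1	677	+	ACA	1
M_pA	IS5_1	845	-	TGA	1
M_pA	IS5_1	1340	+	TCA	1
M_pB	IS5_1	214	+	TAA	4
M_pB	IS5_1	509	-	TTA	2
M_pB	IS5_1	677	+	ACA	1
M_pB	IS5_1	1061	-	TAA	1
M_pB	IS5_1	1477	+	ATA	1
M_Ch	IS5_1	214	+	TAA	3
M_Ch	IS5_1	902	-	TGA	1
M_Ch	IS5_1	1150	+	TCA	1
M_Ch	IS5_1	1333	-	TTA	1
H_pA	IS5_1	456	+	ACA	1
H_pA	IS5_1	1022	-	TGA	1
H_pB	IS5_1	456	+	ACA	1
H_Ch	IS5_1	789	-	TAA	1
L_pA	IS5_1	52	+	TAA	3
L_pA	IS5_1	30	-	TTA	1
L_pB	IS5_1	52	+	TAA	2
M_pA	IS5_1	52	+	TAA	1
M_pA	IS5_1	75	-	ATA	1
H_pA	IS3_1	144	+	CGG	2
H_pA	IS3_1	402	-	GCA	1
H_pA	IS3_1	633	+	CTG	1
H_pA	IS3_1	871	-	GGC	1
H_pA	IS3_1	1099	+	ACG	1
H_pA	IS3_1	1310	-	TGC	1
H_pA	IS3_1	1455	+	CAG	1
H_pB	IS3_1	520	-	GCC	1
H_Ch	IS3_1	964	+	CGT	1
M_pA	IS3_1	755	-	GAC	1
H_pA	IS3_1	40	+	CTC	1
H_pA	IS3_1	71	-	GGA	1
L_pA	IS1595_1	290	+	ATA	3
L_pA	IS1595_1	610	-	TTT	1
L_pB	IS1595_1	290	+	ATA	1
L_pA	IS1595_1	45	+	ATA	7
L_pA	IS1595_1	22	-	TTT	2
L_pA	IS1595_1	68	+	AAT	1
L_pB	IS1595_1	45	+	ATA	4
L_pB	IS1595_1	22	-	TCA	1
L_Ch	IS1595_1	45	+	ATA	2
M_pA	IS1595_1	45	+	ATA	2
M_pA	IS1595_1	68	-	AAT	1
L_pA	IS630_1	388	+	TA	2
L_pA	IS630_1	550	-	TA	1
L_pB	IS630_1	388	+	TA	1
L_pB	IS630_1	820	-	TA	1
L_Ch	IS630_1	388	+	TA	1
M_pA	IS630_1	1024	+	TA	1
L_pA	IS630_1	17	+	TA	2
L_pB	IS630_1	17	-	TA	1
M_pA	IS630_1	63	+	TA	1
L_pA	IS4_1	700	+	TTA	1
L_pA	IS4_1	944	-	TAA	1
M_pA	IS4_1	700	+	TTA	1
M_pA	IS4_1	1210	-	TAA	1
L_pA	IS1182_1	477	+	AACTACCG	1
L_pA	IS1182_1	1388	-	AACTACCG	1
L_pB	IS1182_1	477	+	AACTACCG	1
L_pA	IS5_2	655	+	TTA	1
M_pA	IS5_2	655	-	TTA	1
M_pA	IS5_2	1460	+	TCA	1
H_pA	IS3_2	233	+	GCG	1
H_pB	IS3_2	1330	-	CCA	1
L_pA	IS256_1	1177	+	GTTAGCAA	1
M_pA	IS110_1	530	+		1
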