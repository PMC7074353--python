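Gene	Strand	Location	Length	Anticodon	StartCodon	StopCodon	OVL_ITS
trnI(gat)	H	1-65	65	GAU	-	-	3
trnQ(ttg)	L	69-137	69	UUG	-	-	-1
trnM(cat)	H	137-205	69	CAU	-	-	0
nad2	H	206-1231	1026	-	ATA	TAA	1
trnW(tca)	H	1233-1300	68	UCA	-	-	32
trnC(gca)	L	1333-1397	65	GCA	-	-	2
trnY(gta)	L	1400-1467	68	GUA	-	-	1
cox1	H	1469-3004	1536	-	CGA	TAA	-5
trnL2(taa)	H	3000-3065	66	UAA	-	-	1
cox2	H	3067-3754	688	-	ATG	T	0
trnK(ctt)	H	3755-3825	71	CUU	-	-	0
trnD(gtc)	H	3826-3892	67	GUC	-	-	0
atp8	H	3893-4054	162	-	ATT	TAA	-7
atp6	H	4048-4725	678	-	ATG	TAA	8
cox3	H	4734-5522	789	-	ATG	TAA	2
trnG(tcc)	H	5525-5590	66	UCC	-	-	0
nad3	H	5591-5944	354	-	ATT	TAA	0
trnA(tgc)	H	5945-6012	68	UGC	-	-	-1
trnR(tcg)	H	6012-6078	67	UCG	-	-	4
trnN(gtt)	H	6083-6146	64	GUU	-	-	0
trnS1(gct)	H	6147-6212	66	GCU	-	-	2
trnE(ttc)	H	6215-6281	67	UUC	-	-	-2
trnF(gaa)	L	6280-6347	68	GAA	-	-	-1
nad5	L	6347-8077	1731	-	ATT	TAA	0
trnH(gtg)	L	8078-8145	68	GUG	-	-	-1
nad4	L	8145-9485	1341	-	ATG	TAA	-7
nad4l	L	9479-9769	291	-	ATT	TAA	2
trnT(tgt)	H	9772-9835	64	UGU	-	-	0
trnP(tgg)	L	9836-9902	67	UGG	-	-	10
nad6	H	9913-10428	516	-	ATA	TAA	-1
cob	H	10428-11567	1140	-	ATG	TAG	-2
trnS2(tga)	H	11566-11634	69	UGA	-	-	16
nad1	L	11651-12592	942	-	ATA	TAG	10
trnL1(tag)	L	12603-12666	64	UAG	-	-	4
rrnL	L	12671-13963	1293	-	-	-	18
trnV(tac)	L	13982-14053	72	UGC	-	-	-1
rrnS	L	14053-14751	699	-	-	-	0
control_region	-	14752-16646	1895	-	-	-	-
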