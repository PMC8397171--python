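Gene	Direction	Location	Size	Anticodon	Start Codon	Stop Codon	Intergenic Nucleotides
trnM	F	1–68	68	CAT 32–34
trnI	F	69–133	65	GAT 99–101			0
trnQ	R	131–199	69	TTG 158–160			−3
nad2	F	269–1282	1013		ATT	TAA	69
trnW	F	1281–1348	68	TCA 1312–1314			−2
trnC	R	1341–1403	63	GCA 1372–1374			−8
trnY	R	1404–1468	65	GTA 1435–1437			0
cox1	F	1474–3009	1536		CGA	TAA	5
trnL2 (UUR)	F	3005–3071	67	TAA 3035–3037			−5
cox2	F	3072–3750	679		ATG	T	0
trnK	F	3748–3818	71	CTT 3778–3780			−3
trnD	F	3818–3883	66	GTC 3848–3850			−1
atp8	F	3884–4042	159		ATC	TAA	0
atp6	F	4036–4713	678		ATG	TAA	−7
cox3	F	4713–5501	789		ATG	TAA	−1
trnG	F	5504–5568	65	TCC 5534–5536			2
nad3	F	5566–5922	357		ATA	TAG	−3
trnA	F	5921–5987	67	TGC 5953–5955			−2
trnR	F	5987–6052	66	TCG 6014–6016			−1
trnN	F	6053–6118	66	GTT 6084–6086			0
trnS1 (AGN)	F	6117–6176	60	GCT 6134–6136			−2
trnE	F	6180–6243	64	TTC 6108–6210			3
trnF	R	6244–6308	65	GAA 6276–6278			0
nad5	R	6308–8044	1737		ATT	TAA	−1
trnH	R	8042–8106	65	GTG 8071–8073			−3
nad4	R	8107–9445	1339		ATG	T	0
nad4L	R	9447–9731	285		ATG	TAA	1
trnT	F	9744–9807	64	TGT 9774–9776			12
trnP	R	9808–9871	64	TGG 9840–9842			0
nad6	F	9874–10401	528		ATA	TAA	2
cob	F	10,406–11,554	1149		ATG	TAA	4
trnS2 (UCN)	F	11,561–11,624	64	TGA 11,589–11,591			6
nad1	R	11,638–12,579	942		ATG	TAA	13
trnL1 (CUN)	R	12,581–12,654	74	TAG 12,623–12,625			1
rrnL	R	12,655–13,981	1327				0
trnV	R	13,982–14,044	63	TAC 14,014–14,016			0
rrnS	R	14,045–14,818	774				0
Control region		14,819–15,208	390				0
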