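Gene	Direction	Location	Size	Anticodon	Start Codon	Stop Codon	Intergenic Nucleotides
trnM	F	1–68	68	CAT 32–34
trnI	F	69–134	66	GAT 98–100			0
trnQ	R	132–200	69	TTG 159–161			−3
nad2	F	292–1305	1014		ATT	TAA	91
trnW	F	1304–1371	68	TCA1335–1337			−2
trnC	R	1364–1427	64	GCA 1397–1399			−8
trnY	R	1428–1492	65	GTA 1359–1461			0
cox1	F	1498–3033	1536		CGA	TAA	5
trnL2 (UUR)	F	3029–3095	67	TAA 3059–3061			−5
cox2	F	3096–3774	679		ATG	T	0
trnK	F	3772–3842	71	CTT 3802–3804			−3
trnD	F	3842–3907	66	GTC 3872–3874			−1
atp8	F	3908–4069	162		ATC	TAA	0
atp6	F	4063–4737	675		ATG	TAA	−7
cox3	F	4737–5525	789		ATG	TAA	−1
trnG	F	5528–5594	67	TCC 5558–5560			2
nad3	F	5595–5948	354		ATT	TAG	0
trnA	F	5947–6014	68	TGC 5976–5978			−2
trnR	F	6014–6077	64	TCG 6040–6042			−1
trnN	F	6090–6155	66	GTT 6121–6123			12
trnS1 (AGN)	F	6154–6213	60	GCT 6171–6173			−2
trnE	F	6216–6280	65	TTC 6245–6247			2
trnF	R	6279–6342	64	GAA 6310–6312			−2
nad5	R	6317–8077	1761		ATT	TAA	−26
trnH	R	8075–8141	67	GTG 8109–8111			−3
nad4	R	8142–9480	1339		ATG	T	0
nad4L	R	9482–9772	291		ATA	TAA	1
trnT	F	9780–9844	65	TGT 9811–9813			7
trnP	R	9845–9908	64	TGG 9877–9879			0
nad6	F	9911–10438	528		ATA	TAA	2
cob	F	10,442–11,593	1152		ATG	TAA	3
trnS2 (UCN)	F	11,596–11,662	67	TGA 11,625–11,627			2
nad1	R	11,685–12,626	942		ATG	TAA	22
trnL1 (CUN)	R	12,628–12,702	75	TAG 12,671–12,673			1
rrnL	R	12,703–14,036	1334				0
trnV	R	14,037–14,100	64	TAC 14,069–14,071			0
rrnS	R	14,101–14,876	776				0
Control region		14,877–15,252	376				0
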