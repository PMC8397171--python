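canonical	synonyms
trnM	trnM	trnM(CAT)	tRNA-Met	trn-Met	MET
trnI	trnI	tRNA-Ile	ILE
trnQ	trnQ	tRNA-Gln	GLN
nad2	nad2	ND2	NADH2	NADH dehydrogenase subunit 2
trnW	trnW	tRNA-Trp	TRP
trnC	trnC	tRNA-Cys	CYS
trnY	trnY	tRNA-Tyr	TYR
cox1	cox1	COI	COX1	CO1	coxI	cytochrome c oxidase subunit 1	cytochrome c oxidase subunit I
trnL2	trnL2	trnL2 (UUR)	trnL2(UUR)	trnL(UUR)	tRNA-Leu(UUR)	tRNA-Leu (UUR)	trnL-uur
cox2	cox2	COII	COX2	CO2	coxII	cytochrome c oxidase subunit 2	cytochrome c oxidase subunit II
trnK	trnK	tRNA-Lys	LYS
trnD	trnD	tRNA-Asp	ASP
atp8	atp8	ATP8	ATPase8	ATPase 8	ATP synthase F0 subunit 8
atp6	atp6	ATP6	ATPase6	ATPase 6	ATP synthase F0 subunit 6
cox3	cox3	COIII	COX3	CO3	coxIII	cytochrome c oxidase subunit 3	cytochrome c oxidase subunit III
trnG	trnG	tRNA-Gly	GLY
nad3	nad3	ND3	NADH3	NADH dehydrogenase subunit 3
trnA	trnA	tRNA-Ala	ALA
trnR	trnR	tRNA-Arg	ARG
trnN	trnN	tRNA-Asn	ASN
trnS1	trnS1	trnS1 (AGN)	trnS1(AGN)	trnS(AGN)	tRNA-Ser(AGN)	tRNA-Ser (AGN)	trnS-agn
trnE	trnE	tRNA-Glu	GLU
trnF	trnF	tRNA-Phe	PHE
nad5	nad5	ND5	NADH5	NADH dehydrogenase subunit 5
trnH	trnH	tRNA-His	HIS
nad4	nad4	ND4	NADH4	NADH dehydrogenase subunit 4
nad4L	nad4L	nad4l	ND4L	NADH dehydrogenase subunit 4L
trnT	trnT	tRNA-Thr	THR
trnP	trnP	tRNA-Pro	PRO
nad6	nad6	ND6	NADH6	NADH dehydrogenase subunit 6
cob	cob	cytb	CYTB	Cyt b	cytochrome b	COB
trnS2	trnS2	trnS2 (UCN)	trnS2(UCN)	trnS(UCN)	tRNA-Ser(UCN)	tRNA-Ser (UCN)	trnS-ucn
nad1	nad1	ND1	NADH1	NADH dehydrogenase subunit 1
trnL1	trnL1	trnL1 (CUN)	trnL1(CUN)	trnL(CUN)	tRNA-Leu(CUN)	tRNA-Leu (CUN)	trnL-cun
rrnL	rrnL	lrRNA	16S	16S rRNA	l-rRNA	large subunit ribosomal RNA	rrn16
trnV	trnV	tRNA-Val	VAL
rrnS	rrnS	srRNA	12S	12S rRNA	s-rRNA	small subunit ribosomal RNA	rrn12
control_region	control_region	Control region	control region	D-loop	A+T-rich region	AT-rich region	CR	misc_feature:control
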