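system_id	resolution_A	target	ligand	ligand_mw	shell1	shell2	shell3	dHb_exp_kcal_mol
3ptb_ben	1.7	beta-trypsin	benzamidine	121.2	1	6	7	-4.507
3ptb_pme	1.7	beta-trypsin	p-methylbenzamidine	135.2	1	5	6	-4.412
3ptb_pam	1.7	beta-trypsin	p-aminobenzamidine	136.2	3	4	7	-6.417
3ptb_pmo	1.7	beta-trypsin	p-methoxybenzamidine	151.2	1	6	7	-3.742
3ptb_pad	1.7	beta-trypsin	p-amidinobenzamidine	164.2	2	8	10	-2.935
1k1l	2.5	bovine-trypsin	NAP-piperazine	467.6	5	10	15	-7.863
1k1m	2.2	bovine-trypsin	NAP-4-acetyl-piperazine	508.6	4	12	16	-8.222
1k1i	2.2	bovine-trypsin	NAP-D-pipecolinic-acid	508.6	2	13	15	-10.899
1k1j	2.2	bovine-trypsin	NAP-isopipecolinic-acid-methyl-ester	523.6	3	13	16	-9.465
1jyr	1.55	Grb2-SH2-domain	APS-PTR-VNVQN	1069.0	1	14	15	-7.94
1rlq	NA	C-src-tyrosine-kinase-SH3-domain	RALPPLPRY	1084.3	2	25	27	-10.2
2ke1	NA	autoimmune-regulator	ARTKQTARKS	1150.3	12	15	27	-9.2
2bba	1.65	EphB4-receptor	NYLFSPNGPIARAW	1606.8	12	15	27	-15.5
1jgn	NA	human-polyA-binding-protein	VVKSNLNPNAKEFVPGVKYGNI	2389.8	14	34	48	-14.8
2roc	NA	induced-myeloid-leukemia-cell-differentiation-protein-homolog	EEEWAREIGAQLRRIADDLNAQYERRM	3317.6	14	38	52	-14.3
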