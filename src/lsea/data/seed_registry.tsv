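canonical_id	display_name	synonyms	precursor	enzyme_class	chebi_id	lmsd_id
pge2	PGE2	Prostaglandin E2	AA	COX	CHEBI:15551	LMFA03010003
pgd2	PGD2	Prostaglandin D2	AA	COX	CHEBI:15555	LMFA03010004
pgf2a	PGF2a	Prostaglandin F2alpha|PGF2alpha	AA	COX	CHEBI:15553	LMFA03010002
txb2	TXB2	Thromboxane B2	AA	COX	CHEBI:28728	LMFA03030002
6-keto-pgf1a	6-keto-PGF1a	6-keto Prostaglandin F1alpha	AA	COX	CHEBI:28335	LMFA03010001
15-deoxy-pgj2	15-deoxy-PGJ2	15-deoxy-Delta12,14-PGJ2	AA	COX	CHEBI:34159	LMFA03010021
ltb4	LTB4	Leukotriene B4	AA	LOX	CHEBI:15647	LMFA03020001
ltc4	LTC4	Leukotriene C4	AA	LOX	CHEBI:16978	LMFA03020002
5-hete	5-HETE	5-hydroxyeicosatetraenoic acid|5-HETE acid	AA	LOX	CHEBI:65341	LMFA03060002
12-hete	12-HETE	12-hydroxyeicosatetraenoic acid	AA	LOX	CHEBI:19138	LMFA03060088
15-hete	15-HETE	15-hydroxyeicosatetraenoic acid	AA	LOX	CHEBI:64017	LMFA03060001
5-oxoete	5-OxoETE	5-oxo-eicosatetraenoic acid|5-KETE	AA	LOX	CHEBI:52449	LMFA03060089
lipoxin-a4	Lipoxin A4	LXA4	AA	LOX	CHEBI:6498	LMFA03040001
lipoxin-b4	Lipoxin B4	LXB4	AA	LOX	CHEBI:6499	LMFA03040002
20-hete	20-HETE	20-hydroxyeicosatetraenoic acid	AA	CYP450	CHEBI:34306	LMFA03060009
5(6)-epetre	5(6)-EpETrE	5,6-EET|5(6)-EET	AA	CYP450	CHEBI:34496	LMFA03080002
8(9)-epetre	8(9)-EpETrE	8,9-EET|8(9)-EET	AA	CYP450	CHEBI:34485	LMFA03080003
11(12)-epetre	11(12)-EpETrE	11,12-EET|11(12)-EET	AA	CYP450	CHEBI:34124	LMFA03080004
14(15)-epetre	14(15)-EpETrE	14,15-EET|14(15)-EET	AA	CYP450	CHEBI:34159	LMFA03080005
14,15-dihetre	14,15-DiHETrE	14,15-DHET	AA	CYP450	CHEBI:63969	LMFA03050004
8-iso-pgf2a	8-iso-PGF2a	8-isoprostane|iPF2alpha-III	AA	non_enzymatic	CHEBI:34509	LMFA03110001
11-hete	11-HETE	11-hydroxyeicosatetraenoic acid	AA	mixed	CHEBI:72637	LMFA03060085
pge1	PGE1	Prostaglandin E1|Alprostadil	DGLA	COX	CHEBI:15544	LMFA03010134
pgd1	PGD1	Prostaglandin D1	DGLA	COX	CHEBI:27696	LMFA03010035
15-hetre	15-HETrE	15-hydroxyeicosatrienoic acid	DGLA	LOX	CHEBI:132155	LMFA02000216
9(10)-epome	9(10)-EpOME	9,10-EpOME|Coronaric acid|Leukotoxin	LA	CYP450	CHEBI:38241	LMFA02000037
12(13)-epome	12(13)-EpOME	12,13-EpOME|Vernolic acid|Isoleukotoxin	LA	CYP450	CHEBI:38238	LMFA02000036
9,10-dihome	9,10-DiHOME	Leukotoxin diol	LA	CYP450	CHEBI:72663	LMFA02000014
12,13-dihome	12,13-DiHOME	Isoleukotoxin diol	LA	CYP450	CHEBI:72665	LMFA02000015
9-hode	9-HODE	9-hydroxyoctadecadienoic acid	LA	LOX	CHEBI:34496	LMFA02000217
13-hode	13-HODE	13-hydroxyoctadecadienoic acid	LA	LOX	CHEBI:34154	LMFA02000228
9-oxoode	9-OxoODE	9-KODE|9-oxo-octadecadienoic acid	LA	LOX	CHEBI:84283	LMFA02000389
13-oxoode	13-OxoODE	13-KODE|13-oxo-octadecadienoic acid	LA	LOX	CHEBI:84275	LMFA02000388
maresin-1	Maresin-1	MaR1|Maresin 1	DHA	LOX	CHEBI:79620	LMFA04000047
maresin-2	Maresin-2	MaR2|Maresin 2	DHA	LOX	CHEBI:138637	LMFA04000049
protectin-d1	Protectin D1	PD1|Neuroprotectin D1|NPD1	DHA	LOX	CHEBI:138655	LMFA04000045
protectin-dx	Protectin DX	PDX|10S,17S-DiHDoHE	DHA	LOX	CHEBI:136542	LMFA04000051
resolvin-d1	Resolvin D1	RvD1	DHA	mixed	CHEBI:81559	LMFA04000040
resolvin-d2	Resolvin D2	RvD2	DHA	mixed	CHEBI:81560	LMFA04000041
resolvin-d5	Resolvin D5	RvD5	DHA	mixed	CHEBI:138650	LMFA04000044
17-hdohe	17-HDoHE	17-hydroxydocosahexaenoic acid|17-HDHA	DHA	LOX	CHEBI:72642	LMFA04000028
14-hdohe	14-HDoHE	14-hydroxydocosahexaenoic acid|14-HDHA	DHA	LOX	CHEBI:72625	LMFA04000026
4-hdohe	4-HDoHE	4-hydroxydocosahexaenoic acid|4-HDHA	DHA	LOX	CHEBI:72636	LMFA04000023
19(20)-epdpe	19(20)-EpDPE	19,20-EDP|19(20)-EpDPA	DHA	CYP450	CHEBI:73722	LMFA04000042
16(17)-epdpe	16(17)-EpDPE	16,17-EDP	DHA	CYP450	CHEBI:73695	LMFA04000039
19,20-dihdpa	19,20-DiHDPA	19,20-DiHDoPE	DHA	CYP450	CHEBI:72650	LMFA04000057
resolvin-e1	Resolvin E1	RvE1	EPA	mixed	CHEBI:81554	LMFA03070020
18-hepe	18-HEPE	18-hydroxyeicosapentaenoic acid	EPA	CYP450	CHEBI:132087	LMFA03070028
15-hepe	15-HEPE	15-hydroxyeicosapentaenoic acid	EPA	LOX	CHEBI:131821	LMFA03070027
12-hepe	12-HEPE	12-hydroxyeicosapentaenoic acid	EPA	LOX	CHEBI:72802	LMFA03070026
5-hepe	5-HEPE	5-hydroxyeicosapentaenoic acid	EPA	LOX	CHEBI:131820	LMFA03070023
pge3	PGE3	Prostaglandin E3	EPA	COX	CHEBI:27647	LMFA03010220
txb3	TXB3	Thromboxane B3	EPA	COX	CHEBI:28447	LMFA03030006
9-hotre	9-HOTrE	9-hydroxyoctadecatrienoic acid	LNA	LOX	CHEBI:131825	LMFA02000241
13-hotre	13-HOTrE	13-hydroxyoctadecatrienoic acid	LNA	LOX	CHEBI:131826	LMFA02000245
resolvin-d1-n-3-dpa	Resolvin D1 n-3 DPA	RvD1n-3 DPA	DPA	mixed	CHEBI:145009	LMFA04000063
maresin-1-n-3-dpa	Maresin-1 n-3 DPA	MaR1n-3 DPA	DPA	LOX	CHEBI:145016	LMFA04000066
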