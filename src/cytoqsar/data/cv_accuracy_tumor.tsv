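cell_line	tissue	endpoint	n	r2_5fold	rmse_5fold
A-375	Skin	pIC50	3020	0.430	0.881
A-431	Epithelium	pIC50	2496	0.695	0.610
Caco-2	Colon	pIC50	825	0.577	0.533
Caki-1	Kidney	pIC50	323	NA	NA
Calu-1	Lung	pIC50	177	0.496	0.811
COLO 205	Colon	pIC50	1334	0.700	0.639
HCT-8	Colon	pIC50	980	0.737	0.530
HepG2	Liver	pIC50	16982	0.554	0.762
SH-SY5Y	Nervous	pIC50	826	0.471	0.782
SW-620	Colon	pIC50	1918	0.566	0.698
THP-1	Blood	pIC50	2629	0.684	0.803
U-937	Lymphoid	pIC50	1503	0.669	0.682
A-431	Epithelium	pGI50	373	0.647	0.550
COLO 205	Colon	pGI50	1319	-0.283	1.052
HepG2	Liver	pGI50	653	0.487	0.671
THP-1	Blood	pGI50	114	0.851	0.384
U-937	Lymphoid	pGI50	147	0.882	0.442
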