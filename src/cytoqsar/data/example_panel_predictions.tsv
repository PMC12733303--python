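cell_line	tissue	group	endpoint	paclitaxel	trametinib	dabrafenib
GES1	Stomach	non-tumor	pIC50	7.825	4.979	4.848
HaCaT	Skin	non-tumor	pIC50	7.459	5.187	4.924
HEK293	Kidney	non-tumor	pIC50	6.699	5.329	5.269
HEK-293T	Kidney	non-tumor	pIC50	7.716	5.914	5.130
HUVEC	Endothelium	non-tumor	pGI50	8.436	5.250	5.266
HUVEC	Endothelium	non-tumor	pIC50	7.141	6.743	5.893
MCF-10A	Mammary gland	non-tumor	pIC50	3.803	5.566	5.111
MRC5	Lung	non-tumor	pIC50	9.063	4.953	5.030
PBMC	Blood	non-tumor	pIC50	5.489	6.502	7.128
TERT-RPE1	Retina	non-tumor	pIC50	5.117	5.564	5.293
WI-38	Lung	non-tumor	pIC50	7.036	5.652	4.721
A-431	Skin	tumor	pGI50	8.628	6.182	5.716
A-431	Skin	tumor	pIC50	8.119	5.911	5.334
Caco-2	Colon	tumor	pIC50	7.380	5.258	5.186
COLO205	Colon	tumor	pIC50	8.470	7.579	8.140
HCT-8	Colon	tumor	pIC50	7.292	6.196	6.684
HepG2	Liver	tumor	pIC50	7.173	5.394	5.509
SW-620	Colon	tumor	pIC50	7.519	7.030	5.656
THP-1	Blood	tumor	pGI50	5.385	5.269	5.649
THP-1	Blood	tumor	pIC50	5.631	7.157	6.556
U-937	Lymphoid	tumor	pGI50	8.395	5.773	6.309
U-937	Lymphoid	tumor	pIC50	8.536	6.906	6.566
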