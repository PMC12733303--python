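cell_line	tissue	endpoint	n	r2_5fold	rmse_5fold
BEAS-2B	Lung	pIC50	129	0.497	0.550
BJ	Skin	pIC50	328	0.340	0.854
CCD-18Co	Colon	pIC50	311	0.201	0.395
GES1	Stomach	pIC50	192	0.610	0.503
HaCaT	Skin	pIC50	730	0.872	0.371
HEK-293	Kidney	pIC50	2705	0.695	0.607
HEK-293T	Kidney	pIC50	588	0.826	0.409
HFF	Skin	pIC50	454	0.207	0.873
HFL1	Lung	pIC50	341	-0.298	0.663
HMEC-1	Skin	pIC50	152	0.473	1.029
HUVEC	Endothelium	pIC50	2254	0.553	0.920
MCF-10A	Mammary gland	pIC50	514	0.818	0.357
MRC5	Lung	pIC50	1523	0.688	0.493
NHDF	Skin	pIC50	234	-0.249	0.581
PBMC	Blood	pIC50	1885	0.540	0.969
TERT-RPE1	Retina	pIC50	96	0.623	0.407
WI-38	Lung	pIC50	829	0.786	0.508
HUVEC	Endothelium	pGI50	239	0.631	0.711
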