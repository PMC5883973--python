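# Plasma metabolite concentrations (uM, mean +/- SD) per study group, with
# per-group sample sizes used in the analysis. Groups: Ha = healthy animals,
# 0h..72h = diseased animals at hours after admission.
metabolite	group	mean_uM	sd_uM	n
Isoleucine	Ha	98.8	28.3	10
Isoleucine	0h	147.8	67	19
Isoleucine	3h	122.3	57.4	20
Isoleucine	6h	98.5	53	20
Isoleucine	24h	82.3	36.4	17
Isoleucine	48h	111.5	27.5	14
Isoleucine	72h	106.1	36.5	12
Valine	Ha	227.3	76.2	10
Valine	0h	434.7	182.7	19
Valine	3h	380.6	157	20
Valine	6h	323.6	144.5	20
Valine	24h	232.9	80.6	17
Valine	48h	304.6	56.8	14
Valine	72h	284.9	100.1	12
Leucine	Ha	405.7	111.2	10
Leucine	0h	851.5	421.8	19
Leucine	3h	701	355	20
Leucine	6h	586.4	303.6	20
Leucine	24h	425	145.3	17
Leucine	48h	538.9	144.2	14
Leucine	72h	483.6	137.9	12
Alanine	Ha	236.9	142.3	10
Alanine	0h	398.1	154.2	19
Alanine	3h	341.8	333.4	20
Alanine	6h	274.6	191.6	20
Alanine	24h	226.2	51.5	17
Alanine	48h	293	123.2	14
Alanine	72h	242.2	97	12
3-Hydroxybutyric acid	Ha	61.4	44.6	10
3-Hydroxybutyric acid	0h	94.2	38.9	19
3-Hydroxybutyric acid	3h	129.8	105	20
3-Hydroxybutyric acid	6h	134	146	20
3-Hydroxybutyric acid	24h	84.4	44.2	17
3-Hydroxybutyric acid	48h	111.2	118.2	14
3-Hydroxybutyric acid	72h	124.7	132	12
Isobutyric acid	Ha	10.9	3.7	10
Isobutyric acid	0h	27.1	16.14	19
Isobutyric acid	3h	40	17.8	20
Isobutyric acid	6h	41.2	17.9	20
Isobutyric acid	24h	22.7	8.5	17
Isobutyric acid	48h	21.6	9.8	14
Isobutyric acid	72h	21.6	10.6	12
Acetic acid	Ha	54	17	10
Acetic acid	0h	234.24	536	19
Acetic acid	3h	110.31	54.44	20
Acetic acid	6h	86.9	30.87	20
Acetic acid	24h	116.7	115.5	17
Acetic acid	48h	77.5	62.3	14
Acetic acid	72h	67.6	43.7	12
Acetone	Ha	6.7	8.6	10
Acetone	0h	10	9.6	19
Acetone	3h	14.6	11.8	20
Acetone	6h	15.4	14.6	20
Acetone	24h	15.4	11.4	17
Acetone	48h	16.6	25.5	14
Acetone	72h	26.3	33.7	12
Choline	Ha	68.5	29.3	10
Choline	0h	66.8	29.5	19
Choline	3h	47.5	18.2	20
Choline	6h	32	13.5	20
Choline	24h	29.6	11.7	17
Choline	48h	32.7	12.3	14
Choline	72h	33	14.6	12
Creatine	Ha	168.8	74.5	10
Creatine	0h	702.9	397	19
Creatine	3h	628.4	431.3	20
Creatine	6h	533.5	401.6	20
Creatine	24h	309	144	17
Creatine	48h	336	103.4	14
Creatine	72h	305	146.3	12
Phosphocreatine + creatinine	Ha	108	30.8	10
Phosphocreatine + creatinine	0h	399.3	153.5	19
Phosphocreatine + creatinine	3h	378.4	226.8	20
Phosphocreatine + creatinine	6h	333.2	221	20
Phosphocreatine + creatinine	24h	219	111.2	17
Phosphocreatine + creatinine	48h	219	75.5	14
Phosphocreatine + creatinine	72h	207.8	95.7	12
Formic acid	Ha	51	17.8	10
Formic acid	0h	27.3	10.4	19
Formic acid	3h	24.6	9.3	20
Formic acid	6h	24.7	9.2	20
Formic acid	24h	43.4	16	17
Formic acid	48h	44.5	14.3	14
Formic acid	72h	54.3	22.3	12
D-Glucose	Ha	1400	245.5	10
D-Glucose	0h	1811	1196	19
D-Glucose	3h	1351	709.5	20
D-Glucose	6h	1816	1226.4	20
D-Glucose	24h	1697	652	17
D-Glucose	48h	1783	439	14
D-Glucose	72h	1714.4	1423	12
Glycine	Ha	171.2	76.1	10
Glycine	0h	223.8	90.5	19
Glycine	3h	160.3	137	20
Glycine	6h	142.2	86	20
Glycine	24h	176.3	68.2	17
Glycine	48h	198	73.2	14
Glycine	72h	170	77.25	12
Phenylalanine	Ha	57.2	16.7	10
Phenylalanine	0h	112.2	52.7	19
Phenylalanine	3h	95.2	50	20
Phenylalanine	6h	77.6	44.8	20
Phenylalanine	24h	83	66.5	17
Phenylalanine	48h	71.3	17.9	14
Phenylalanine	72h	71.6	21	12
Proline	Ha	108.7	34.2	10
Proline	0h	84	38.8	19
Proline	3h	92.8	14.5	20
Proline	6h	71.2	21.3	20
Proline	24h	43	14.5	17
Proline	48h	63.3	32.2	14
Proline	72h	48	16.6	12
Pyruvic acid	Ha	21.8	16.7	10
Pyruvic acid	0h	49.6	56	19
Pyruvic acid	3h	51.2	21.3	20
Pyruvic acid	6h	56	26.8	20
Pyruvic acid	24h	48.8	22.6	17
Pyruvic acid	48h	42.4	24.4	14
Pyruvic acid	72h	39.5	24.3	12
Tyrosine	Ha	44.64	23.9	10
Tyrosine	0h	53.39	16.64	19
Tyrosine	3h	50.74	27.90	20
Tyrosine	6h	41.22	17.07	20
Tyrosine	24h	36.54	14.87	17
Tyrosine	48h	35.89	12.76	14
Tyrosine	72h	34.62	14.93	12
Dimethyl sulfone	Ha	7.91	1.94	10
Dimethyl sulfone	0h	15.06	8.74	19
Dimethyl sulfone	3h	14.11	9.1	20
Dimethyl sulfone	6h	13.19	9.37	20
Dimethyl sulfone	24h	11.91	6.63	17
Dimethyl sulfone	48h	11.15	4.93	14
Dimethyl sulfone	72h	10.54	4.87	12
Allantoin	Ha	71.8	35.05	10
Allantoin	0h	501.4	238.9	19
Allantoin	3h	423.4	213	20
Allantoin	6h	376.4	200.2	20
Allantoin	24h	256.8	169.2	17
Allantoin	48h	268.3	155.8	14
Allantoin	72h	238.7	165.7	12
GPC	Ha	32.9	55.8	10
GPC	0h	44.7	27	19
GPC	3h	34.9	27.4	20
GPC	6h	27.6	23.4	20
GPC	24h	25	17.8	17
GPC	48h	25.5	25.4	14
GPC	72h	28.8	29.9	12
Histidine	Ha	98.6	50.6	10
Histidine	0h	151.5	62.2	19
Histidine	3h	120.3	86.9	20
Histidine	6h	110.7	68.9	20
Histidine	24h	87.4	32.9	17
Histidine	48h	94.8	30.3	14
Histidine	72h	78.8	32.5	12
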