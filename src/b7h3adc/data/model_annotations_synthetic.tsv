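model_id	phenotype	b7h3_level	b7h3_positive	RB1_state	TP53_state	ATR_state	CHD1_state	BRCA2_state	slfn11	repstress_z	rb1_score_z	nauc_median	observed_response
LuCaP145.2	SCNPC	3.2	True	biallelic_loss	altered	wt	wt	wt	True	1.9	2.1	0.24	R
LuCaP93	SCNPC	4.1	True	biallelic_loss	altered	wt	wt	wt	True	1.7	1.8	0.28	R
LuCaP145.1	SCNPC	2.8	True	biallelic_loss	altered	wt	wt	wt	True	1.5	1.6	0.34	R
LuCaP49	SCNPC	3.6	True	biallelic_loss	altered	wt	wt	wt	False	1.4	1.5	0.39	R
LuCaP173.1	SCNPC	2.5	True	biallelic_loss	altered	wt	wt	wt	False	1.3	1.4	0.39	R
LuCaP173.2	DNPC	3.0	True	biallelic_loss	altered	wt	wt	wt	False	1.6	1.7	0.34	R
LuCaP176	DNPC	4.4	True	biallelic_loss	altered	wt	wt	wt	True	1.8	1.9	0.24	R
LuCaP35CR	ARPC	28.0	True	wt	altered	wt	wt	wt	True	0.4	0.3	0.49	R
LuCaP170.2	ARPC	22.0	True	wt	altered	wt	wt	wt	True	1.2	0.5	0.53	R
LuCaP23.1	ARPC	6.1	True	wt	altered	wt	wt	wt	True	1.1	0.4	0.60	R
LuCaP23.1CR	ARPC	5.8	True	wt	altered	wt	wt	wt	True	0.3	0.2	0.62	R
LuCaP77	ARPC	5.6	True	wt	altered	wt	wt	wt	True	0.2	0.1	0.65	R
LuCaP77CR	ARPC	5.4	True	wt	altered	wt	wt	wt	True	0.1	0.0	0.69	R
LuCaP81	ARPC	4.9	True	biallelic_loss	altered	wt	wt	wt	True	1.5	1.6	0.54	R
LuCaP92	ARPC	5.2	True	biallelic_loss	altered	wt	wt	wt	True	1.4	1.5	0.56	R
LuCaP141	ARPC	18.0	True	wt	altered	wt	altered	wt	False	0.0	-0.1	0.70	R
LuCaP141CR	ARPC	16.0	True	wt	altered	wt	altered	wt	False	-0.1	-0.2	0.71	R
NCI-PC155	ARPC	24.0	True	wt	wt	altered	wt	wt	False	0.1	0.0	0.63	R
LuCaP167	ARPC	5.6	True	wt	wt	wt	wt	wt	False	-0.9	-1.0	1.00	NR
LuCaP96	ARPC	6.3	True	wt	wt	wt	wt	biallelic_loss	False	-0.7	-0.8	0.98	NR
LuCaP73	ARPC	4.8	True	wt	wt	wt	wt	wt	False	-1.0	-1.1	0.99	NR
LuCaP86.2	ARPC	5.9	True	wt	wt	wt	wt	wt	False	-0.8	-0.9	0.97	NR
LuCaP105	ARPC	5.1	True	wt	wt	wt	wt	wt	False	-1.1	-1.2	1.00	NR
LuCaP147	ARPC	6.6	True	wt	wt	wt	wt	wt	False	-0.6	-0.7	0.99	NR
LuCaP167CR	ARPC	4.5	True	wt	wt	wt	wt	wt	False	-1.2	-1.3	1.00	NR
LuCaP70CR	ARPC	5.7	True	wt	altered	wt	wt	wt	False	-0.5	-0.6	0.97	NR
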