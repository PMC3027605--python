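characteristic	category	M0	PM	LM
gender	Male	14	21	27
gender	Female	11	16	9
location	Right colon	11	11	4
location	Left colon	9	22	22
location	Rectum	5	4	10
t_status	T1	0	0	0
t_status	T2	0	1	4
t_status	T3	21	25	30
t_status	T4	4	11	1
t_status	unknown	0	0	1
n_status	N0	19	17	13
n_status	N+	6	19	22
n_status	unknown	0	0	1
stage	1	0	1	0
stage	2	16	5	3
stage	3	9	13	7
stage	4	0	18	26
presentation	Metachrone	25	19	8
presentation	Synchrone	0	18	26
presentation	unknown	0	0	2
differentiation	Good	0	3	3
differentiation	Moderate	21	27	17
differentiation	Poor	3	5	6
differentiation	Other type	0	2	0
msi_status	Stable	21	33	30
msi_status	Low	2	0	0
msi_status	High	0	1	0
adjuvant_treatment	No	16	25	34
adjuvant_treatment	Chemo	6	12	2
adjuvant_treatment	unknown	3	0	0
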