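patient	recurrent	sex	age	grade	hbv_pre	hbv_post	recurrence_month	organ	cirrhosis
HCC1	1	M	48	III	1	0	8	Liver	1
HCC4	1	M	59	II	1	1	6.5	Liver	0
HCC5	1	M	67	II	0	0	18	Liver	1
HCC11	1	F	57	II-III	0	0	16	Lung	1
HCC2	1	M	43	II	1	0	19	Liver	1
HCC3	1	M	42	III	1	0	14.5	Liver	1
HCC6	1	M	41	III	1	0	1.5	Lung	1
HCC8	1	M	42	III	1	0	11	Liver	1
HCC10	1	M	59	III	1	0	6	Liver	1
HCC-C2	0	M	55	I-II	1	0		NA	1
HCC-C6	0	M	51	II	1	0		NA	1
HCC-C8	0	M	64	I	1	1		NA	1
HCC-C9	0	M	40	II	1			NA	1
HCC-C11	0	M	62	I	1	0		NA	1
HCC-C12	0	M	40	II-III	1	1		NA	1
HCC-C13	0	M	49	I-II	1	0		NA	1
HCC-C14	0	M	59	II	1			NA	1
HCC-C15	0	M	49	II	1	0		NA	1
HCC-C16	0	M	49	II-III	1			NA	1
HCC-C18	0	M	57	I	1	0		NA	1
HCC-C19	0	M	41	II-III	1	1		NA	1
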