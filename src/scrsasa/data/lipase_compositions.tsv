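accession	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A0A3R9KNJ9	62	21	4	22	4	10	10	48	5	11	37	7	2	12	33	21	26	8	16	29
A0A3R9DUJ4	58	13	10	24	4	18	11	39	4	9	34	16	4	16	30	20	29	5	18	32
A0A427T6P4	65	18	13	22	2	9	12	50	5	14	40	9	5	11	33	33	34	5	19	37
A0A3R9KMI2	69	20	8	20	4	11	18	39	9	14	38	11	3	14	28	24	21	3	17	33
A0A3R9EQB2	45	8	7	14	6	7	5	37	7	9	28	8	3	9	17	18	22	3	11	24
A0A3R9F8T1	44	9	3	10	4	13	14	31	3	4	26	3	2	0	20	11	20	3	3	29
A0A3R9DV90	51	19	13	20	4	20	9	52	8	13	31	7	7	15	25	39	27	10	19	30
A0A427T2R3	54	34	8	26	2	6	21	38	14	10	48	5	2	11	30	8	26	3	5	29
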