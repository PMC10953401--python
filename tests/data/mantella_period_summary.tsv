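Period	Marks	1	2	3	4	5	6
1	1090	219	55	17	255	90	15
2	295		43	42	41	62	37
3	115			35	7	2	0
4	686				174	81	30
5	403					107	13
6	141						1
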