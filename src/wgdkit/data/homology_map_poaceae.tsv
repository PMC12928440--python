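ancestral_chromosome	Oryza sativa	Sorghum bicolor	Eragrostis tef	Oropetium thomaeum	Zoysia japonica	Sporobolus alterniflorus
A1	1	3	3A, 3B	3	5, 6	2, 5, 3, 8
A2	2	4, 1	1A, 1B	1	7, 8	9, 13, 6, 15
A3	3	1	4A, 4B	4	1, 2	4, 7, 1, 12
A4	4	6	7A, 7B	6	11, 12	23, 26, 25, 30
A5	5	9	9A, 9B	5	17, 18	1, 12, 18, 22
A6	6	2, 10	2A, 2B	2	19, 20	14, 21, 10, 11
A7	7	2	5A, 5B	7	3, 4	19, 27, 24, 28
A8	8	7	8A, 8B	9	13, 14	16, 17, 20, 29
A9	9	2, 10	2A, 2B	2	19, 20	14, 21, 10, 11
A10	10	4, 1	1A, 1B	1	7, 8	9, 13, 6, 15, 4
A11	11	5	6A, 6B	8	9, 10	16, 17, 7, 31
A12	12	8	10A, 10B	10	15, 16	19, 27, 6, 4
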