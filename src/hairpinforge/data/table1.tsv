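name	sequence	size_nt	reads	mfei	unigene_id	unigene_length_bp	is_star	strand
miR6135a	TGGTAAGTTGGTCAATTGGC	20	107	1.49	PUT-183a-Panax_ginseng-10400	390	0	+
miR6135b	TGGTAAGTTGGTCAATTGGC	20	107	1.48	PUT-183a-Panax_ginseng-1888	3603	0	+
miR6135c	GGGTAAGTTGGTCAATTGAC	20	17	1.45	PUT-183a-Panax_ginseng-1888	3603	0	-
miR6135d	GGGTAAGTTGGTCAATTGAC	20	17	1.66	PUT-183a-Panax_ginseng-5770	779	0	+
miR6135e.1	GGGTAAGTTGGTCAATTGAC	20	17	1.47	PUT-183a-Panax_ginseng-7458	799	0	+
miR6135e.2	AATTGACTAATAGAATACTGACAC	24	21	1.47	PUT-183a-Panax_ginseng-7458	799	0	+
miR6135f	GAGTAAGTTGGTCAATTGGC	20	4	1.32	PUT-183a-Panax_ginseng-1153	514	0	+
miR6135g	GAGTAAGTTGGTCAATTGGC	20	4	1.63	PUT-183a-Panax_ginseng-11661	155	0	+
miR6135h	GTAAGTTGGTCAATTGGC	18	5	1.02	PUT-183a-Panax_ginseng-17044	767	0	+
miR6135i	AATTGGCCAATAGAATACTGACAC	24	30	1.43	PUT-183a-Panax_ginseng-5770	779	0	-
miR6135j	AATTGACTAATAGAATACTGACAC	24	21	1.32	FW1NBNE01BCPRY	474	0	+
miR6135k	CGTGTCGATACTGTATTGGT	20	3	1.54	PUT-183a-Panax_ginseng-1587	475	0	+
miR6136a.1	TAGACGACGGTTGTATGACCG	21	32	1.40	FW1NBNE01BEGNB	465	0	+
miR6136a.2	ACGGGTGAGTAAGATAAGGGGTAT	24	88	1.40	FW1NBNE01BEGNB	465	0	+
miR6136b	TCATACAACCGTCGTCTATAC	21	70	1.45	FW1NBNE01BEGNB	465	0	-
miR6136b*	TATAAATGATGGTTGTATGAC	21	1	1.45	FW1NBNE01BEGNB	465	1	-
miR6137a	ATGAAAATTGTCGCTATAGATC	22	3	2.13	FW1NBNE01A9PXQ	425	0	+
miR6137b	ATGAAAATTGTCGCTATAGATC	22	3	1.56	PUT-183a-Panax_ginseng-4023	606	0	+
miR6138	TACGTTTGGATTGAAGGAATGAAA	24	13	0.98	PUT-183a-Panax_ginseng-10763	517	0	+
miR6139	AAGAATCATTGGGAAGGGAAGAAA	24	9	1.15	FW1NBNE01AHR0J	608	0	+
miR6140a	AATGTTTGTAGAATAGTTTGTGTC	24	3	1.38	FW1NBNE01A9GRG	391	0	+
miR6140b	AATGTTTGTAGAATAATTTGTGTA	24	2	1.14	PUT-183a-Panax_ginseng-19298	1417	0	+
miR6140c	GCTGAGGTGGAGTATGCCACATC	23	5	1.32	FW1NBNE01ATMKX	436	0	+
miR6140d	CGTTGATGTGGCATACTTCACC	22	3	1.12	PUT-183a-Panax_ginseng-8684	972	0	+
miR6141	TAACTAAATCTGGCCTGTAGCGGA	24	7	1.56	FW1NBNE01B00A0	391	0	+
miR6142	GACGATTTTTTGGGCTATGACGAC	24	5	0.93	FW1NBNE01CDN8L	235	0	+
miR6143a	AGTACTGTATTGGGCATGAAG	21	13	1.20	FW1NBNE01CELC5	535	0	+
miR6143b-5p	ACAATGTCGACACGCAGGCGGAGA	24	2	1.24	PUT-183a-Panax_ginseng-16660	399	0	+
miR6143b-3p	CAGCACTGTATTGAACATGAA	21	4	1.24	PUT-183a-Panax_ginseng-16660	399	0	+
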