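family	target_function	unigene_id	penalty
MIR6135	Zinc finger CCCH-type antiviral protein	FW1NBNE01BOG42	1.5
MIR6135	beta-Cyanoalanine synthase	PUT-183a-Panax_ginseng-3189	2.5
MIR6135	Mapkkk3	PUT-183a-Panax_ginseng-5059	3
MIR6135	Unknown	FW1NBNE01CDUDE	1.5
MIR6135	Unknown	Contig2012	2.5
MIR6135	Unknown	PUT-183a-Panax_ginseng-2440	3
MIR6136	Unknown	PUT-183a-Panax_ginseng-1090	3
MIR6136	Unknown	PUT-183a-Panax_ginseng-11673	3
MIR6137	Armadillo/beta-catenin-like	PUT-183a-Panax_ginseng-3440	2.5
MIR6137	Protein phosphatase	PUT-183a-Panax_ginseng-4655	2.5
MIR6137	Repeat-containing protein	PUT-183a-Panax_ginseng-8005	3
MIR6137	Unknown	Contig872	3
MIR6138	Asparagine synthetase	FW1NBNE01BSZXK	2
MIR6139	Serine/threonine-protein phosphatase	FW1NBNE01BWTI7	2.5
MIR6139	ZIP transporter	PUT-183a-Panax_ginseng-20083	2.5
MIR6139	3-Hydroxybutyryl-CoA dehydratase	Contig1795	3
MIR6139	UDP-sugar transporter	PUT-183a-Panax_ginseng-9068	3
MIR6139	Unknown	FW1NBNE01B23TH	2.5
MIR6139	Unknown	FW1NBNE01AQA9Q	2.5
MIR6140	Phytanoyl-CoA dioxygenase-like protein	PUT-183a-Panax_ginseng-6406	2.5
MIR6140	KH domain-containing protein	PUT-183a-Panax_ginseng-11439	2.5
MIR6140	Casein kinase 2 subunit beta	PUT-183a-Panax_ginseng-10659	2.5
MIR6140	Villin	PUT-183a-Panax_ginseng-2502	3
MIR6140	Mitochondrial chaperonin-60	PUT-183a-Panax_ginseng-18641	3
MIR6140	DnaJ-like protein	FW1NBNE01CCFHV	3
MIR6140	Phytochrome	FW1NBNE01A44YJ	3
MIR6140	Unknown	PUT-183a-Panax_ginseng-19392	3
MIR6140	Unknown	PUT-183a-Panax_ginseng-13359	3
MIR6143	Homeobox-leucine zipper protein	Contig703	2.5
MIR6143	Acyl-CoA dehydrogenase	FW1NBNE01BR56P	3
MIR6143	Unknown	Contig1700	3
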