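# Haplogroup U6 tree: reconstruction for motif-based classification.
# One node per line: name <TAB> parent <TAB> defining variant tokens
# (space separated) <TAB> optional geographic label.
# The root motif gives the variants separating U6 from basal haplogroup U.
# Nodes whose published defining-mutation lists are established carry them
# verbatim; internal nodes without an established motif carry package-chosen
# diagnostics (HVS-I diagnostics from the 8-way sorting where available,
# otherwise placeholder coding transitions) adequate for path scoring but
# not authoritative.
U6	-	3348 16172
U6a	U6	7805 14179 16219 16278	MAG
U6a1	U6a	2218
U6a1a	U6a1	16189
U6a1a1	U6a1a	16239
U6a1a1a	U6a1a1	5300
U6a1a1a2	U6a1a1a	13071
U6a1b	U6a1	16235
U6a1b1	U6a1b	6045
U6a1b1b	U6a1b1	2158 10336 14034 16145
U6a2	U6a	16189 15626	EAF
U6a2a	U6a2	13934
U6a2a3	U6a2a	4936 9100 9128 10172 16295 5894C 9335A
U6a2a3a	U6a2a3	15626!
U6a2b	U6a2	15383 16354
U6a2b1	U6a2b	15314 16184
U6a2c	U6a2	195
U6a3	U6a	16189 650
U6a3a	U6a3	14364
U6a3a1	U6a3a	9329
U6a3a1b	U6a3a1	8598
U6a3b	U6a3	10101
U6a3b1	U6a3b	7867
U6a3b1a	U6a3b1	16311
U6a3c	U6a3	146 291.1A 960d 1809 5554A 6182 11272 15380
U6a3e	U6a3	185 3337 4021 8705 12097 13569 13928 16362 16399
U6a3f	U6a3	150 185 310 8763
U6a3g	U6a3	150 3826
U6a5	U6a	5655
U6a5a	U6a5	9136
U6a5a1	U6a5a	11191
U6a5b	U6a5	3714 16184 16234
U6a6	U6a	1703	MAG
U6a6a	U6a6	16079
U6a6a1	U6a6a	9031
U6a7	U6a	4218
U6a7a	U6a7	152 980 3945 5471
U6a7a1	U6a7a	5120
U6a7a1a	U6a7a1	2672 11929
U6a7a1b	U6a7a1	150
U6a7a1c	U6a7a1	152!
U6a7a2	U6a7a	6815
U6a7a2a	U6a7a2	14034
U6a7a2a1	U6a7a2a	11941
U6a7b	U6a7	2833	MAG
U6a7b1	U6a7b	5237 12950C
U6a7b1a	U6a7b1	455.1T 960.1C 11818C 12940 13879
U6a8	U6a	143 8282 10172 11539 750! 16189	MAG
U6b'd	U6	16219 16311
U6b	U6b'd	4904	COS
U6b1	U6b	9738 15431
U6b1a	U6b1	2352 16163	CAN
U6b1a1	U6b1a	7700	CAN
U6b1a2	U6b1a	6734	CAN
U6b1a3	U6b1a	15697 16092	CAN
U6b1b	U6b1	10143	MAG
U6b2	U6b	4062 12535 13637 15355	MAG
U6b3	U6b	16278
U6b3a	U6b3	235
U6b4	U6b	5442 16051
U6b5	U6b	5773 8951 14053 16111 16362
U6d	U6b'd	3591	MAG
U6d1	U6d	16261
U6d3	U6d	16174	MAG
U6c	U6	16169 16189	MED
U6c1	U6c	4965
U6c1a	U6c1	12406 16111
U6c1b	U6c1	16086	CAN
U6c1c	U6c1	5964 12092A 15617
U6c2	U6c	194	MAG
U6c2a	U6c2	3866
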