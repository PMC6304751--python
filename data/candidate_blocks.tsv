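haplotype	chrom	start_mb	end_mb
3	3	73.3	73.7
8	5	20.1	20.5
10	8	144.9	145.3
11	8	145.1	145.5
13	9	19.0	19.4
14	9	126.9	127.3
15	10	61.8	62.2
16	12	35.8	36.2
19	16	57.2	57.6
20	17	28.7	29.1
21	17	28.9	29.3
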