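repeat	exon	intergenic	intron
p2	7909	45439	78991
p3	6655	10027	14969
p4	761	4689	6308
p5	207	1071	1623
p6	70	236	247
compound	3776	16794	26801
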