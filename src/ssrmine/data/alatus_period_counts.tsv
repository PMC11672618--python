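period	n	total_bp
2	245271	7045666
3	50220	1188063
4	18107	628736
5	4108	162205
6	1156	45000
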