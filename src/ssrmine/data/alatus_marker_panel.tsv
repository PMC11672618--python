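locus	na	ne	ho	he	shannon_i	pic
Hqd1	8	4.2582	0.1724	0.7786	1.7101	0.7370
Hqd2	10	4.7380	0.3103	0.8028	1.7962	0.7601
Hqd3	9	4.5459	0.1034	0.7937	1.7266	0.7482
Hqd6	6	4.2690	0.4138	0.7792	1.5529	0.7270
Hqd8	4	1.9157	0.5172	0.4864	0.8398	0.4145
Hqd12	3	2.6869	0.4483	0.6388	1.0333	0.5488
Hqd14	8	3.6805	0.1379	0.7411	1.5372	0.6870
Hqd32	7	5.2399	0.2069	0.8234	1.7807	0.7843
Hqd33	7	3.5787	0.1724	0.7332	1.5565	0.6907
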