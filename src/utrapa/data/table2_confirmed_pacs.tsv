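no	location	start	end	pac	expression	gene	region
5	Chr5	6912890	6912958	6912913	273	AT5G20450	UTR
6	Chr2	15606647	15606694	15606648	80	AT2G37150	UTR_intron
7	Chr1	4499266	4499411	4499335	646	AT1G13190	UTR_intron
9	Chr2	12586290	12586343	12586314	61	AT2G29290	UTR
10	Chr5	1844980	1845038	1845031	49	AT5G06120	UTR_intron
11	Chr3	4594130	4594133	4594130	48	AT3G13920	UTR_intron
12	Chr1	846598	846644	846602	36	AT1G03410	UTR
13	Chr5	24654185	24654190	24654185	35	AT5G61310	UTR_intron
14	Chr2	13272650	13272664	13272651	33	AT2G31150	UTR
16	Chr1	20260492	20260495	20260494	26	AT1G54270	UTR_intron
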