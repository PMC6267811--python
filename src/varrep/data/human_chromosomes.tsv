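chromosome	n_genes	cds_length_nt	varisnp_neutral_observed
1	2037	3483903	45856
2	1238	2517642	31391
3	1071	1965098	24735
4	745	1365661	16936
5	882	1601648	19148
6	1035	1735760	22495
7	901	1609177	21764
8	668	1135640	16239
9	770	1382150	19117
10	727	1322286	17489
11	1278	2005315	28704
12	1033	1776908	20797
13	324	634435	7401
14	614	1079560	13972
15	589	1189858	14846
16	858	1451775	22351
17	1184	1971211	26518
18	268	534152	6644
19	1467	2277812	34032
20	540	811690	11340
21	233	342226	5194
22	439	712404	10412
X	840	1296174	8557
Y	45	67500	51
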