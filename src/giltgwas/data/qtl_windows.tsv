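chrom	start_bp	end_bp	marker_first	marker_last	genvar_pct	rank	p_value
12	14910939	15006310	M1GA0016274	ASGA0053410	9.7332	1	0.0001
6	68823187	68890361	ASGA0091283	ALGA0035583	0.3064	35	0.001
1	291202322	291277150	ALGA0009830	M1GA0001507	0.6121	10	0.003
3	26517667	26631496	MARC0007734	ALGA0018104	0.5091	15	0.003
7	43190587	43400560	ALGA0040857	ASGA0033098	0.1673	75	0.003
7	75121635	75460294	INRA0026429	H3GA0022045	7.1362	2	0.003
15	42527231	43052985	H3GA0044224	ALGA0114567	1.7467	3	0.003
3	11143547	11286978	H3GA0008684	ASGA0013430	0.5400	13	0.004
9	142232369	142338853	ASGA0044888	ASGA0044901	1.4283	4	0.004
10	18347386	18665600	ASGA0046792	DRGA0010326	0.3992	24	0.004
3	11960567	12093180	ALGA0017578	ALGA0017611	1.0870	6	0.005
14	138428984	138850067	DRGA0014684	ALGA0082115	0.4572	19	0.005
1	121626075	121978687	M1GA0001099	ASGA0004239	0.4196	21	0.006
3	21596232	22794763	ASGA0013855	ASGA0094123	0.1765	70	0.006
3	27054931	27208960	MARC0085816	ALGA0124353	1.1368	5	0.006
6	127194648	127655907	MARC0001714	ASGA0029572	0.3900	25	0.006
15	148542045	148722557	ASGA0071543	ASGA0071569	0.1564	83	0.007
8	15600021	15671195	DRGA0008334	ASGA0037920	0.2543	41	0.008
8	109067052	109213652	H3GA0025237	MARC0017963	0.2658	39	0.008
11	55668610	55844999	ALGA0062350	ALGA0062355	0.3136	34	0.008
16	44362264	44481215	ALGA0090494	MARC0073104	0.2123	50	0.008
18	50837228	51030054	DRGA0017050	ASGA0105879	0.5142	14	0.008
2	133313068	133376955	INRA0009763	MARC0038747	0.2935	36	0.009
10	40710979	40868229	MARC0038064	ALGA0058443	0.0985	149	0.009
15	142893866	142992475	MARC0112236	ALGA0087841	0.3401	29	0.009
2	157110989	157223320	MARC0039166	M1GA0003373	0.2571	40	0.01
2	157270386	157362402	H3GA0008275	ALGA0017005	0.4738	17	0.01
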