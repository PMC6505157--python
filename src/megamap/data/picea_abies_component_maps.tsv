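cluster	lg	markers	bins	length_cM	max_gap_cM
cluster1	I	975	421	385.5	8.0
cluster1	II	701	305	249.2	9.6
cluster1	III	859	394	324.0	4.6
cluster1	IV	771	323	298.7	14.5
cluster1	V	761	311	273.2	8.9
cluster1	VI	648	292	241.0	8.4
cluster1	VII	682	331	314.0	8.4
cluster1	VIII	775	339	307.0	5.6
cluster1	IX	792	332	283.3	5.4
cluster1	X	648	289	231.6	7.0
cluster1	XI	677	253	200.6	3.7
cluster1	XII	784	334	281.6	9.3
cluster2	I	1159	553	439.9	21.1
cluster2	II	863	366	289.0	9.4
cluster2	III	1069	479	381.1	7.1
cluster2	IV	970	452	350.9	8.6
cluster2	V	1116	499	395.6	9.5
cluster2	VI	915	399	270.7	4.6
cluster2	VII	923	443	380.8	13.4
cluster2	VIII	943	454	367.26	9.8
cluster2	IX	786	364	295.6	5.9
cluster2	X	960	454	342.7	6.9
cluster2	XI	1025	411	269.2	4.0
cluster2	XII	919	437	360.7	11.1
cluster3	I	1967	1185	414.1	8.8
cluster3	II	1456	864	289.8	10.9
cluster3	III	1738	1075	346.4	5.2
cluster3	IV	1531	916	303.0	27.0
cluster3	V	1649	1032	342.6	15.1
cluster3	VI	1456	894	269.5	8.4
cluster3	VII	1625	1013	321.9	7.9
cluster3	VIII	1465	904	315.6	6.6
cluster3	IX	1589	911	285.1	7.4
cluster3	X	1564	917	272.7	7.1
cluster3	XI	1440	818	233.6	3.0
cluster3	XII	1526	950	312.3	14.3
consensus	I	2172		414.1	
consensus	II	1608		250.3	
consensus	III	1940		342.5	
consensus	IV	1704		303.0	
consensus	V	1865		275.0	
consensus	VI	1622		240.2	
consensus	VII	1769		321.0	
consensus	VIII	1609		305.9	
consensus	IX	1738		285.0	
consensus	X	1709		273.1	
consensus	XI	1608		233.4	
consensus	XII	1712		312.3	
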