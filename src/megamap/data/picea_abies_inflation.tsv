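cluster	lg	observed_length_cM	mean_estimated_length_cM	sd_cM
cluster1	I	385.5	245.5	5.2
cluster1	II	249.2	168.8	4.7
cluster1	III	324.0	195.8	5.8
cluster1	IV	298.7	204.7	5.0
cluster1	V	273.2	195.7	4.6
cluster1	VI	241.0	161.8	4.7
cluster1	VII	314.0	223.6	5.3
cluster1	VIII	307.0	203.6	4.9
cluster1	IX	283.3	194.0	4.9
cluster1	X	231.6	164.4	3.6
cluster1	XI	200.6	141.8	4.7
cluster1	XII	281.6	194.4	4.9
cluster2	I	439.9	252.3	6.1
cluster2	II	289.0	192.9	4.4
cluster2	III	381.1	218.6	5.8
cluster2	IV	350.9	215.6	5.7
cluster2	V	395.6	218.4	9.0
cluster2	VI	270.7	170.0	4.7
cluster2	VII	380.8	248.7	6.3
cluster2	VIII	367.26	226.7	5.7
cluster2	IX	295.6	185.3	6.8
cluster2	X	342.7	193.6	4.5
cluster2	XI	269.2	147.0	4.8
cluster2	XII	360.7	209.6	9.1
cluster3	I	414.2	204.8	7.3
cluster3	II	289.8	166.4	2.8
cluster3	III	346.4	168.5	3.9
cluster3	IV	303.0	167.0	3.5
cluster3	V	342.6	180.0	5.1
cluster3	VI	269.5	142.2	2.9
cluster3	VII	321.9	175.9	3.7
cluster3	VIII	315.6	179.2	4.3
cluster3	IX	285.1	157.2	3.0
cluster3	X	272.7	141.5	2.7
cluster3	XI	233.6	119.6	3.0
cluster3	XII	312.3	168.7	3.1
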