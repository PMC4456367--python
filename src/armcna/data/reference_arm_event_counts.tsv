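arm	sc_whole_arm	sc_focal	ccc_whole_arm	ccc_focal
1p	1	4	3	3
1q	1	2	2	4
2p	0	4	2	2
2q	0	4	1	2
3p	0	5	3	3
3q	2	6	5	6
4p	1	3	2	3
4q	1	8	2	1
5p	0	2	2	1
5q	1	4	1	1
6p	1	4	3	0
6q	1	5	1	4
7p	1	7	1	3
7q	0	4	1	4
8p	1	8	7	7
8q	1	8	12	4
9p	0	4	2	4
9q	0	3	6	3
10p	0	3	1	0
10q	0	3	1	0
11p	0	4	2	1
11q	0	5	2	6
12p	0	2	4	2
12q	0	5	1	2
13q	2	6	4	1
14q	2	7	2	1
15q	0	7	1	6
16p	1	3	2	1
16q	1	4	5	5
17p	7	5	0	6
17q	4	8	1	4
18p	4	1	0	0
18q	4	3	0	1
19p	0	5	0	4
19q	0	3	1	3
20p	1	2	1	3
20q	1	6	3	5
21q	1	4	6	1
22q	1	6	0	4
Xp	5	2	3	0
Xq	5	2	3	1
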