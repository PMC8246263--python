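chrom	length_cM
1	98.5
2	103.9
3	82.7
4	88.6
5	90.2
6	79.0
7	89.1
8	76.2
9	75.1
10	77.9
11	87.9
12	63.9
13	67.3
14	66.4
15	59.0
16	57.8
17	60.6
18	59.4
19	56.7
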