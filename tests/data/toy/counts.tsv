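2	1	1	0
3	3	0	1
1	1	0	0
5	5	5	5
4	0	0	0
2	2	2	0
3	3	3	3
1	1	1	0
2	2	0	2
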