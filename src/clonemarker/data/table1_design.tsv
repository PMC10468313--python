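cultivar	clone_id	n_replicates
CH	4	3
CH	76	3
CH	95	3
CH	548	3
SB	1	2
SB	107	2
SB	159	3
SB	242	2
SB	530	3
CS	c46	2
CS	169	2
CS	170	2
CS	338	3
CS	412	3
M	181	3
M	346	1
M	347	3
M	348	3
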