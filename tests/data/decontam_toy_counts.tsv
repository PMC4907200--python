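otu_id	E1	E2	N1	X1
O1	20	10	50	5
O2	500	300	2	0
O3	480	190	0	0
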