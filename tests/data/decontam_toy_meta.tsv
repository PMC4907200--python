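sample_id	habitat	site	kingdom
E1	downwind	L01	bacteria
E2	upwind	L01	bacteria
N1	ntc	control	bacteria
X1	extraction_control	control	bacteria
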