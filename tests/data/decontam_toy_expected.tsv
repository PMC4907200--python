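otu_id	E1	E2
O2	462	281
O3	480	190
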