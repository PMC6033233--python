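contig0	0	500	promoter
contig0	450	850	gene_body	0	+
contig1	100	600	enhancer
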