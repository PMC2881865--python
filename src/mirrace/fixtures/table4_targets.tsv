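mirna_id	target_accession	target_protein	conserved_gene	gsp	nested_gsp
ptrmir156	FJ502237	Pt-SPL9	AT2G42200	TTAAAGGGACCAATGAATCTGCTGGTTGGAGT	ACAGGTTGAGCGACGGATTTGGTATGG
ptrmir156	FJ502238	Pt-SPL13	AT5G50670	CTCCCAATGAAAGGGAATTGTTTGAG	GGTATCACTGGCTGCGGACCCATCAT
ptrmir164	FJ619349	Pt-NAC1	AT5G61430	TCAATAATTCCAAAGACAATCAAGGGCTACT	AGGGCTACTGGGCCAGCAGAACTTG
ptrmir167	UC46-16450	Pt-ARF8	AT5G37020	ATGACGGTCACTTACTCCCATGGGTCGT	CAAGCAGTAGGAGACAAATCTTAACACAC
ptrmir171	GQ505957	Pt-SCL6	AT4G00150	GCATAAGAGAAGCCCACTGCCCACCAT	ATCGGTGAGATTTCGGAGAAAGATTTGTAAGC
ptrmir319	GQ505958	Pt-TCP4	AT3G15030	ATGGCGAGAATCAGAGGAAGCAGAGGA	CATCTTCGCCTTGGATTCGTGCTGG
ptrmir482a	UC46-36616	Pt-PRS5	AT4G10780	GAGCTCCCGGGATCTCGAATCTTCTGAGTATACT	TCTTGGATTTTCTCCAAGTTGGCATC
ptrmir1446	GU072592	Pt-GRAS	IPR005202	TTCGAAGGCGGCGTGGCGTTGGC	CGCGGTTGGCGAGGCTTTCGAT
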