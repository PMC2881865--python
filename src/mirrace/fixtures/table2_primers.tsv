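mirna_id	gsp1	gsp2	gsp3
ptrmir156	TTTTTTTTTTGTGCTCACTCTCTTCTG	GGAGTAGAAATGACAGAAGAGAGTGAG	TGACAGAAGAGAGTGAGCAC
ptrmir164	TTTTTTTTTTGCACGTGCCCTGCTTCT	GGAGTAGAAATGGAGAAGCAGGGCACG	TGGAGAAGCAGGGCACGTGCA
ptrmir167	TTTTTTTTTTTCAGATCATGCTGGCAG	GGAGTAGAAATGAAGCTGCCAGCATGA	TGAAGCTGCCAGCATGATCTGA
ptrmir171	TTTTTTTTTTGGAGATATTGACGCGGC	GGAGTAGAAATTGAGCCGCGTCAATAT	TTGAGCCGCGTCAATATCTCC
ptrmir319	TTTTTTTTTTGGGAGCTCCCTTCAGTC	GGAGTAGAAATTGGACTGAAGGGAGCT	TTGGACTGAAGGGAGCTCCC
ptrmir482a	TTTTTTTTTTCATGGGTGGAGTAGGGA	GGAGTAGAAATCTTCCCTACTCCACCC	TCTTCCCTACTCCACCCATGCC
ptrmir482b	TTTTTTTTTTAATGGGAGGCATAGGGA	GGAGTAGAAATCTTCCCTATGCCTCCC	TCTTCCCTATGCCTCCCATTCC
ptrmir1446	TTTTTTTTTTTTGAAGCAGAGAGTTCA	GGAGTAGAAAATCTGAACTCTCTGCTT	ATCTGAACTCTCTGCTTCAA
ptrmir435	TTTTTTTTTTCCGACTCCAATTCCGGA	GGAGTAGAAATTATCCGGAATTGGAGT	TTATCCGGAATTGGAGTCGG
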