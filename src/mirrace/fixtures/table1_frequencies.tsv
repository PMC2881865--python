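mirna_id	race5_pt	race5_ath
ptrmir156	1(1/16); 10(14/16)	10(8/12); 9(4/12)
ptrmir164	9(2/16); 10(12/16); 12(2/16)	10(13/13)
ptrmir167	9(12/15)	9(9/12)
ptrmir171	13(10/20); 10(10/20)	12(1/12); 11(1/12); 10(10/12)
ptrmir319	10(15/15)	10(13/13)
ptrmir482a	10(17/18)	8(7/8)
ptrmir482b		8(8/9)
ptrmir1446	10(12/16)	13(10/10)
ptrmir435		
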