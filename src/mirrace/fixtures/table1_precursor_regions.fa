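>ptrmir156
UACUGACAGAAGAGAGUGAGCACACG
>ptrmir164
GAUGGAGAAGCAGGGCACGUGCAUU
>ptrmir167
GUUGAAGCUGCCAGCAUGAUCUGAA
>ptrmir171
UCAUUGAGCCGCGUCAAUAUCUCCUU
>ptrmir319
UGCUUGGACUGAAGGGAGCUCCCAUU
>ptrmir482a
AUAUCUUCCCUACUCCACCCAUGCCAU
>ptrmir482b
AAUUUCUUCCCUAUGCCUCCCAUUCCUAU
>ptrmir1446
UGGAAUCUGAACUCUCUGCUUCAAAUU
>ptrmir435
GGUUAUCCGGAAUUGGAGUCGGCUG
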