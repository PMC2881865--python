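>ptrmir156
UGACAGAAGAGAGUGAGCAC
>ptrmir164
UGGAGAAGCAGGGCACGUGCA
>ptrmir167
UGAAGCUGCCAGCAUGAUCUGA
>ptrmir171
UUGAGCCGCGUCAAUAUCUCC
>ptrmir319
UUGGACUGAAGGGAGCUCCC
>ptrmir482a
UCUUCCCUACUCCACCCAUGCC
>ptrmir482b
UCUUCCCUAUGCCUCCCAUUCC
>ptrmir1446
AUCUGAACUCUCUGCUUCAA
>ptrmir435
UUAUCCGGAAUUGGAGUCGG
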