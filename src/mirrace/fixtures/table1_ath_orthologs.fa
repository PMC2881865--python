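>ptrmir156
UGACAGAAGAGAGUGAGCAC
>ptrmir164
UGGAGAAGCAGGGCACGUGCA
>ptrmir167
UGAAGCUGCCAGCAUGAUCUGA
>ptrmir171
UUGAGCCGUGCCAAUAUCACG
>ptrmir319
UUGGACUGAAGGGAGCUCCC
>ptrmir482a
UCUUCCCUACUCCUCCCAUUCC
>ptrmir482b
UCUUCCCUACUCCUCCCAUUCC
>ptrmir1446
UUCUGAACUCUCUCCCUCAA
>ptrmir435
UUAUCCGGUAUUGGAGUUGA
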