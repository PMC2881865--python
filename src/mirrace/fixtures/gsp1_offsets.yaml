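# per-miRNA GSP1 core offsets (delta): how many nucleotides the 17-nt
# reverse-complement core backs away from the mature 3' end
ptrmir156: 0
ptrmir164: 1
ptrmir167: 0
ptrmir171: 0
ptrmir319: 0
ptrmir482a: 2
ptrmir482b: 2
ptrmir1446: 0
ptrmir435: 0
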