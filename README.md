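# mirrace

Primer design and sequence analysis for validating the exact termini of
computationally predicted plant miRNAs by miR-RACE.

## The problem

EST- and genome-based homology searches predict plant miRNAs by the
thousand, but unlike protein-coding genes, a mature miRNA has no sequence
landmark marking where it starts and ends: prediction places it in a
precursor hairpin only approximately, and the first and last nucleotides —
which set phasing, target complementarity, and the cleavage register —
remain unverified. miR-RACE resolves both termini experimentally: the
small-RNA fraction is polyadenylated, ligated to a 5' adaptor, and reverse
transcribed with an anchored oligo-dT primer, after which two RACE-style
PCRs read each end of the molecule from the adaptor on the opposite side.
The step that makes this work is the pair of gene-specific primers, each
covering exactly 17 nucleotides of the candidate mature

```
GSP1 (5' RACE) = T×10 + revcomp(mature[L−17−δ .. L−δ])        δ ∈ {0,1,2}
GSP2 (3' RACE) = GGAGTAGAAA + mature[1 .. 17]
GSP3 (qPCR)    = mature
```

— long enough to be specific, short enough that the terminus under test is
determined by sequencing, not by the primer. This package implements the
computational side of the workflow for *Poncirus trifoliata* (trifoliate
orange) style studies:

* **homology prediction** — seed-anchored (positions 2–8) scanning of ESTs
  against known matures, ≤ 3 non-seed mismatches, precursor-window folding
  and a six-criteria stem-loop filter (fold score, ≤ 4 substitutions,
  one-arm localization, stem-loop formation, no loop/break, ≤ 6
  mature:star duplex mismatches);
* **primer design** — GSP1/GSP2/GSP3 construction, engineered mismatch
  variants, Wallace/nearest-neighbor melting temperatures, predicted
  product sizes (60 bp and 87 bp for a 20-nt mature);
* **target prediction** — ungapped duplex scanning under position-specific
  caps (≤ 1 mismatch in 1–9, none at 10–11, ≤ 2 from 12 on, ≤ 4 total,
  ≤ 2 consecutive, no gaps);
* **RACE clone analysis** — chemistry trimming, terminus voting and
  consensus reconstruction, `pos(count/total)` frequency tables, and
  RLM-5'RACE cleavage-site mapping in a 100-nt window;
* **synthetic data** — seed-deterministic generators for precursors with
  engineered duplex mismatches, ESTs with implanted hairpins, RACE clone
  reads, and degradome-style fragments, each with recorded ground truth.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Design the primer trio for ptr-miR156 from the packaged reference set:

```python
from mirrace import fixtures
from mirrace.primers import design_primer_set

mature = next(s for s in fixtures.table1_mirnas() if s.id == "ptrmir156")
ps = design_primer_set(mature, fixtures.gsp1_offsets()[mature.id])
```

prints (via the fields of `ps`):

```
mature  : UGACAGAAGAGAGUGAGCAC  (L = 20)
GSP1    : TTTTTTTTTTGTGCTCACTCTCTTCTG   Tm 72 C
GSP2    : GGAGTAGAAATGACAGAAGAGAGTGAG   Tm 78 C
GSP3    : TGACAGAAGAGAGTGAGCAC          Tm 60 C
products: 60 bp (5' RACE), 87 bp (3' RACE)
```

GSP1 is ten T's (annealing to the poly(A) tail) plus the reverse
complement of the mature's last 17 nt; GSP2 is the last ten adaptor
nucleotides plus the mature's first 17 nt; the predicted gel bands are the
60/87-bp products the protocol excises. The same trio for all nine
packaged miRNAs reproduces the published primer table exactly
(`mirrace design --mirnas ... --offsets ... --out primers.tsv`).

End-to-end prediction on synthetic data — implant a hairpin carrying a
2-substitution variant of a known miRNA into a random EST and scan:

```python
from mirrace.homology import MatureMiRNA, predict_mirnas
from mirrace.simulate import make_precursor, make_est, mutate_nonseed, random_mature

known = random_mature(21, seed=7)
implant = mutate_nonseed(known, 2, seed=7)          # 2 non-seed substitutions
prec, _ = make_precursor(implant, 0, seed=7)        # perfect-duplex hairpin
ests, _ = make_est([prec], n_decoys=3, est_len=400, seed=8)
for c in predict_mirnas([MatureMiRNA("known-mir", known)], ests):
    print(c.est_id, c.strand, c.start, c.mature, c.substitutions,
          c.report.fold_score, c.report.passed)
```

```
est_implant_0  +198  UGCUAAAGAUAACUACAUAAC  subs=2  fold=-293  pass=True
```

The implanted variant is recovered at its recorded position with its two
substitutions counted; the dinucleotide-shuffled decoy ESTs yield nothing.

A `mirrace` console script exposes the same operations as subcommands
(`predict`, `design`, `targets`, `race`, `cleavage`, `simulate`,
`show-config`), each writing a TSV plus a reproducibility manifest.

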