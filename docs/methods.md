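# Methods

`mirrace` implements the computational machinery around miR-RACE, an
experimental strategy for validating the exact 5' and 3' termini of
computationally predicted plant miRNAs. The package covers four analyses —
homology-based candidate prediction, RACE primer construction, target-site
prediction, and RACE-clone interpretation — plus seeded generators that
produce every input class with recorded ground truth.

## Primer construction and the RACE chemistry

The library-preparation chemistry is fixed: small RNAs are polyadenylated,
ligated to a 44-nt 5' RNA adaptor, and reverse-transcribed with an anchored
oligo-dT primer (`ATTCTAGAGGCCGAGGCGGCCGACATG-d(T)30-VN`). A cloned cDNA
therefore reads `[5' adaptor][mature][A×30][RT tail]`. Three primers are
derived from a candidate mature of length L (DNA form), each covering
exactly 17 mature nucleotides in its specific core:

* **GSP1** (5' RACE, reverse) = `T×10` + reverse complement of the 17-mer
  ending δ nucleotides before the mature 3' end (δ ∈ {0,1,2});
* **GSP2** (3' RACE, forward) = the last 10 adaptor nucleotides
  (`GGAGTAGAAA`) + mature positions 1–17;
* **GSP3** (qPCR forward) = the full mature.

The 17-nt core is the method's central design compromise: long enough for
primer specificity, short enough that the terminus under test is read from
the opposite adaptor side rather than dictated by the primer. δ defaults
to 0; the published primer set uses δ = 1 for miR164 and δ = 2 for
miR482a/b, shipped as a per-miRNA offsets file rather than modeled — the
published offsets are data, not the output of a stated rule.

Predicted product sizes follow from segment arithmetic. The anchored
oligo-dT consumes exactly 30 A's, with its VN dinucleotide overlapping the
two 3'-terminal mature bases, so

* 5' product = len(mirRacer5) + 4 adaptor bases + (L − δ) + 10 poly-T
  = 40 + L − δ,
* 3' product = 10 adaptor-tail + L + 30 dT + 27 RT-tail = 67 + L,

which gives 60 bp and 87 bp for a 20-nt mature. Both formulas are affine
in L with slope 1. Melting temperatures default to the Wallace rule
(2·(A+T) + 4·(G+C) °C), with a nearest-neighbor backend (Biopython
`Tm_NN`) behind the same call; the protocol names no formula, and the
Wallace rule is the conventional quick estimate for primers of this size.

Engineered mismatch-variant primers (validating the protocol's tolerance of
1–3 terminal mismatches) substitute the terminal-most k core positions by
the fixed transversion A↔C, G↔T, so variant sets are deterministic.

## Homology scan and the six-criteria hairpin filter

Candidate prediction follows the classical EST homology search: the seed
(positions 2–8 from the miRNA 5' end) of each known mature is aligned
exactly against both strands of each EST; every hit yields a same-length
"raw miRNA"; raw miRNAs with more than 3 mismatches outside the seed are
discarded. Position 1 lies outside the stated seed and is counted as
non-seed. Windows of EST context (default extents 60/100/150 nt per side,
best-scoring fold kept) are folded and filtered by six criteria:

1. fold score ≤ −18 (pseudo-kcal; see below) — the "high negative MFE"
   requirement, which no published threshold quantifies, so the default is
   a conventional pre-miRNA screening magnitude and fully configurable;
2. ≤ 4 substitutions between the candidate mature and the known mature;
3. mature localized on one arm of the hairpin;
4. a stem-loop forms with ≥ 50% of mature positions paired;
5. no terminal-loop overlap and no unpaired run longer than 2 nt inside
   the mature or its star ("no loop or break", strictest common reading);
6. ≤ 6 mismatches in the mature:miRNA* duplex, where an unpaired mature
   position counts as one mismatch.

Whether criterion 2's substitution budget includes seed positions is left
configurable; by construction the scan never admits seed mismatches, so the
default behavior counts only non-seed substitutions.

### Folding model

The folder is a Nussinov-style maximum-score dynamic program over nested
structures: G:C = −3, A:U = −2, G:U = −1 pseudo-kcal per pair, minimum
hairpin loop 3 nt. The six criteria need pairing topology and a fold
score, not calibrated free energies, and the simple model is exhaustively
testable: for every sequence ≤ 14 nt the DP provably equals a brute-force
enumeration of all nested structures (500 random cases in the test suite).
Ties between equal-score structures are broken by a secondary score term
(+1 per pair touching the mature span, scale-separated so it can never
change the primary optimum) and then by a fixed traceback preference
(leave the 3'-most base unpaired when score-equal, else pair it with the
5'-most eligible partner). Folding is deterministic. The O(n³) fill is
JIT-compiled with numba when available, with an equivalent pure-numpy
fallback.

### Star inference on embedded hairpins

Under maximum-score pairing, random context around an implanted hairpin
folds too — isolated mature bases can pair far-away context bases. Star
inference therefore walks the mature 5'→3' and keeps the longest
*consistent duplex chain*: partner indices must descend by 1–3 per step
(bulges within the break tolerance), and larger jumps split the chain.
The star span is the chain's opposing positions shifted by the Dicer-style
2-nt 3' overhang (configurable 0–2). The arm call (5p/3p) and the
criterion-5 break checks operate on this chain-derived span, which makes
the filter robust to stray context pairs while still rejecting matures
that straddle the terminal loop (their chain covers < 50% of the mature).

## Target prediction

Targets are ungapped complementary sites scanned over sense transcripts:
every length-L window is classified per miRNA position as Watson–Crick,
G:U wobble, or mismatch (the site is read 3'→5' against the miRNA).
Default caps: ≤ 1 mismatch in positions 1–9, none at the cleavage site
(10–11), ≤ 2 from position 12 to the miRNA 3' end, ≤ 4 total, no more
than 2 consecutive. The "12 to 21/24" phrasing is implemented as position
12 through the last miRNA position, whatever its length. The independent
region caps plus the total cap is the only reading consistent with all the
stated numbers. Wobbles weigh 1.0 by default (the graphical wobble/WC
distinction never states a weight); 0.5 is available, with weighted sums
rounded half-up before comparison against the integer caps, and only
full-weight positions counting toward consecutive runs. A Schwab-style
preset (1 mismatch in 2–12, 3 after 12) ships as an alternative.

## RACE clone analysis

Trimming locates the adaptor signature (mirRacer5+`GAAA` for 5' clones,
`GGAGTAGAAA` for 3' clones — checked in that order because the latter is a
suffix of the former) on either strand, then the homopolymer tract.
Because the chemistry contributes tracts of exact length (10 T from GSP1,
30 A from the anchored dT), a run longer than that length donates its
excess back to the insert — this disambiguates matures that themselves end
in A. Runs ≥ 8 are accepted (slippage margin below the guaranteed 10).

Each trimmed insert is anchored on the candidate precursor by exact match
of its primer-side 17-nt core (5' clones: last 17 nt; 3' clones: first 17
nt), inserts that do not anchor are excluded and reported
(cross-contamination). 5' clones vote on the 5' terminus and 3' clones on
the 3' terminus; the modal pair defines the consensus mature, and full
frequency tables are rendered in the conventional `pos(count/total)`
notation (modal ties break toward the smaller position).

Cleavage mapping anchors 5'-truncated sense fragments on the target
transcript by exact prefix (20 nt), keeps 5' ends within ±50 nt of the
complementary-site midpoint ("100-nt window"; the centering convention is
ours, the window size is the protocol's), and reports counts also in
miRNA coordinates: a fragment starting opposite miRNA nucleotide i is
counted at position i, so canonical slicing appears as a mode at 10.

## Synthetic-data generators

All generators are seed-deterministic (byte-identical output per seed).

* `make_precursor` builds `[pad][mature][loop][star][pad]` (pads 8 nt,
  loop 6 nt by default) where the star is the reverse complement of the
  mature with exactly k engineered non-pairing substitutions. Engineering
  is *provably safe* against the folding model: substituted bases pair the
  opposite mature base not at all and every nearby base strictly weaker
  than the duplex pair they would displace; unpaired mature bases must
  not be able to re-pair with neighbors' partners (no register slides);
  mismatches are placed as isolated positions or adjacent pairs (runs ≤ 2,
  within the break tolerance) with at least one paired position between
  blocks. Pads and loop are homopolymers of a base chosen to be strictly
  score-losing against the adjacent duplex ends. The generator verifies
  the contract by folding (realized mismatch set = engineered set for
  k ≤ 6) and raises `GeometryError` for matures that cannot host the
  requested pattern — batch callers advance the seed stream until the
  requested number of feasible draws is reached (deterministic rejection
  sampling). Random matures start with U (the canonical plant 5' base)
  and cap homopolymer runs at 3 nt, as real matures do; longer runs make
  stem registers degenerate.
* `make_est` implants precursors at recorded offsets/strands in uniform
  A/C/G/T background (default 400 nt, 300 nt in the test harness); decoys
  are Altschul–Erickson dinucleotide shuffles of the precursors
  (composition preserved, structure destroyed).
* `simulate_race_clones` builds reads per the amplicon structure with a
  categorical terminus-noise distribution over offsets −2..+2.
* `simulate_degradome_clones` starts sense fragments at the programmed cut
  (opposite miRNA nucleotide 10 by default) with probability
  `on_target_frac`, elsewhere in the window otherwise.

What the generators deliberately do not emulate: sequencing errors inside
inserts (configurable substitution rate is out of scope for the default
conditions), chromatogram artifacts, realistic EST composition bias,
expression levels, or genome-scale EST volumes. Passing the implant-
recovery suite therefore demonstrates the pipeline's correctness under its
stated rules, not its precision/recall on real EST collections.

## Problem sizes in the shipped harnesses

The test suite and acceptance script run the pipeline at desk scale: ESTs
of 300–400 nt with single implants (100 implant-and-recover trials),
10 feasible precursor draws for each engineered mismatch count 0–8
(22-nt matures, comfortably inside the feasible range for high k), the
full 2^12 mismatch-pattern enumeration for target rules, and 500 random
≤ 14-nt sequences for the folding oracle. The published nine-miRNA
experimental outcomes (clone frequencies, expression panels, the 62,344-
EST scan) are not recomputed; the published sequences, primers, offsets,
frequency strings, and target-gene primers ship as packaged fixtures and
serve as the regression surface for the constructive rules.

## Known limitations

* The pairing model has no loop penalties or stacking; random context
  folds more than a thermodynamic model would, which the duplex-chain
  logic compensates for but does not eliminate.
* Criterion 1's threshold is on the pseudo-kcal scale of this model, not
  comparable to RNAfold free energies.
* `reconstruct_mature` anchors clones by an exact 17-nt core match; bases
  outside the core are not re-verified against the precursor, so isolated
  sequencing errors there do not discard a clone, but a clone whose core
  itself is corrupted is excluded rather than aligned.
* Minus-strand coordinates report the forward-strand start of the hit
  region; consumers wanting strand-local coordinates must convert.
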