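"""Construction of the miR-RACE gene-specific primers (GSP1/GSP2/GSP3).

The RACE chemistry fixes a 44-nt 5' RNA adaptor ligated ahead of the
polyadenylated small RNA and an anchored oligo-dT reverse-transcription
primer, so a cloned cDNA reads

    [5' adaptor][mature miRNA][A x 30][RT-primer tail]

Three primers are derived from a candidate mature of length L (DNA form):

* GSP1 (5' RACE, reverse): ten T's (pairing the poly(A) tail) followed by
  the reverse complement of a 17-nt window ending ``delta`` nt before the
  mature 3' end (``delta`` in 0-2 allows the window to back away from an
  uncertain terminus);
* GSP2 (3' RACE, forward): the last ten adaptor nucleotides (GGAGTAGAAA)
  followed by mature positions 1-17;
* GSP3 (qPCR forward): the full mature sequence.

Every GSP core covers exactly 17 mature nucleotides — enough for primer
specificity while leaving the terminus under test to be read from the
opposite adaptor side.  Predicted product sizes follow from the chemistry:
the anchored oligo-dT consumes exactly 30 A's with its VN dinucleotide
overlapping the two 3'-terminal mature bases, which yields 60 bp (5' RACE)
and 87 bp (3' RACE) for a 20-nt mature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import (
    AlphabetError,
    NucSequence,
    diff_positions,
    dna,
    reverse_complement,
)

CORE_LEN = 17

# deterministic transversion used for engineered primer-end mismatches
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class RaceChemistry:
    """The fixed adaptor/primer constants of the miR-RACE protocol."""

    adaptor5: str = "CGACUGGAGCACGAGGACACUGACAUGGACUGAAGGAGUAGAAA"  # 44 nt RNA
    rt_primer_tail: str = "ATTCTAGAGGCCGAGGCGGCCGACATG"  # + d(T)30 + VN
    mirracer5: str = "GGACACTGACATGGACTGAAGGAGTA"
    mirracer3: str = "ATTCTAGAGGCCGAGGCGGCCGACATG"
    polyT_len: int = 10
    adaptor_tail_len: int = 10
    core_len: int = CORE_LEN
    dT_len: int = 30

    def __post_init__(self) -> None:
        ad = self.adaptor5_dna
        if self.mirracer5 not in ad:
            raise ValueError("mirRacer5 must be a substring of the DNA adaptor")
        if self.mirracer3 != self.rt_primer_tail:
            raise ValueError("mirRacer3 must equal the RT-primer tail")

    @property
    def adaptor5_dna(self) -> str:
        return self.adaptor5.replace("U", "T")

    @property
    def adaptor_tail(self) -> str:
        """Last 10 adaptor nucleotides: the GSP2 prefix (GGAGTAGAAA)."""
        return self.adaptor5_dna[-self.adaptor_tail_len :]

    @property
    def adaptor_remainder(self) -> int:
        """Adaptor bases 3' of the mirRacer5 annealing site (= 4)."""
        ad = self.adaptor5_dna
        return len(ad) - (ad.index(self.mirracer5) + len(self.mirracer5))


@dataclass
class PrimerSet:
    """GSP1/GSP2/GSP3 for one miRNA, with Tm and predicted product sizes."""

    mirna_id: str
    gsp1: NucSequence
    gsp2: NucSequence
    gsp3: NucSequence
    offset: int  # delta, 0-2
    tm: dict[str, float] = field(default_factory=dict)
    predicted_len5: int = 0
    predicted_len3: int = 0
    mismatch_positions: tuple[int, ...] = ()  # core positions, variants only


class PrimerDesignError(ValueError):
    pass


def estimate_tm(primer: NucSequence, method: str = "wallace") -> float:
    """Melting temperature in deg C.

    ``wallace``: 2(A+T) + 4(G+C).  ``nn``: nearest-neighbor thermodynamics
    via Biopython.  DNA only.
    """
    if "U" in primer.residues:
        raise AlphabetError("Tm estimation requires a DNA primer")
    seq = primer.residues
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nn":
        from Bio.SeqUtils import MeltingTemp

        return float(MeltingTemp.Tm_NN(seq))
    raise ValueError(f"unknown Tm method {method!r}")


def predict_amplicon_lengths(
    L: int, delta: int = 0, chem: RaceChemistry | None = None
) -> tuple[int, int]:
    """Predicted 5' and 3' RACE product sizes (bp) for a mature of length L.

    5' product: mirRacer5 + adaptor remainder + (L - delta) mature bases +
    the 10 poly(T) of GSP1.  3' product: 10-nt adaptor tail + L + d(T)30 +
    mirRacer3 (the anchored VN overlaps the mature, adding nothing).
    Both are affine in L with slope 1.
    """
    chem = chem or RaceChemistry()
    len5 = len(chem.mirracer5) + chem.adaptor_remainder + (L - delta) + chem.polyT_len
    len3 = chem.adaptor_tail_len + L + chem.dT_len + len(chem.mirracer3)
    return len5, len3


def gsp1_core(mature_dna: str, delta: int) -> str:
    """Reverse complement of the 17-nt window ending delta nt before the 3' end."""
    L = len(mature_dna)
    window = mature_dna[L - CORE_LEN - delta : L - delta]
    return reverse_complement(NucSequence("w", window, "DNA")).residues


def design_primer_set(
    mature: NucSequence,
    delta: int = 0,
    chem: RaceChemistry | None = None,
    tm_method: str = "wallace",
) -> PrimerSet:
    """Design the GSP1/GSP2/GSP3 trio for one candidate mature miRNA."""
    chem = chem or RaceChemistry()
    if delta not in (0, 1, 2):
        raise PrimerDesignError(f"delta must be 0-2, got {delta}")
    m = dna(mature)
    L = len(m)
    if L < chem.core_len + delta:
        raise PrimerDesignError(
            f"{mature.id!r}: mature length {L} < core {chem.core_len} + delta {delta}"
        )
    g1 = "T" * chem.polyT_len + gsp1_core(m.residues, delta)
    g2 = chem.adaptor_tail + m.residues[: chem.core_len]
    g3 = m.residues
    ps = PrimerSet(
        mirna_id=mature.id,
        gsp1=NucSequence(f"{mature.id}_GSP1", g1, "DNA", strict=True),
        gsp2=NucSequence(f"{mature.id}_GSP2", g2, "DNA", strict=True),
        gsp3=NucSequence(f"{mature.id}_GSP3", g3, "DNA", strict=True),
        offset=delta,
    )
    ps.tm = {
        "gsp1": estimate_tm(ps.gsp1, tm_method),
        "gsp2": estimate_tm(ps.gsp2, tm_method),
        "gsp3": estimate_tm(ps.gsp3, tm_method),
    }
    ps.predicted_len5, ps.predicted_len3 = predict_amplicon_lengths(L, delta, chem)
    return ps


def design_mismatch_variants(
    mature: NucSequence,
    k: int,
    end: str,
    chem: RaceChemistry | None = None,
    delta: int = 0,
) -> list[PrimerSet]:
    """Primer variants m1..mk with 1..k engineered terminal core mismatches.

    ``end='five_prime'`` mutates the GSP1 core at the positions covering the
    mature 3' terminus (the bases GSP1 anneals to at the end under test);
    ``end='three_prime'`` mutates the GSP2 core at the mature 5' terminus.
    Substitutions follow the fixed transversion rule A<->C, G<->T so the
    variants are deterministic.
    """
    chem = chem or RaceChemistry()
    if not 1 <= k <= 3:
        raise PrimerDesignError(f"k must be 1-3, got {k}")
    if end not in ("five_prime", "three_prime"):
        raise PrimerDesignError(f"end must be five_prime|three_prime, got {end!r}")
    true_set = design_primer_set(mature, delta, chem)
    out = []
    for j in range(1, k + 1):
        ps = design_primer_set(mature, delta, chem)
        if end == "five_prime":
            seq = list(ps.gsp1.residues)
            # core starts after the poly-T; its first bases read the mature 3' end
            positions = [chem.polyT_len + i for i in range(j)]
            for p in positions:
                seq[p] = _TRANSVERSION[seq[p]]
            ps.gsp1 = NucSequence(
                f"{mature.id}m{j}_GSP1", "".join(seq), "DNA", strict=True
            )
            assert len(diff_positions(ps.gsp1, true_set.gsp1)) == j
            ps.mismatch_positions = tuple(i + 1 for i in range(j))
        else:
            seq = list(ps.gsp2.residues)
            # core starts after the adaptor tail; first bases are mature 5' end
            positions = [chem.adaptor_tail_len + i for i in range(j)]
            for p in positions:
                seq[p] = _TRANSVERSION[seq[p]]
            ps.gsp2 = NucSequence(
                f"{mature.id}m{j}_GSP2", "".join(seq), "DNA", strict=True
            )
            assert len(diff_positions(ps.gsp2, true_set.gsp2)) == j
            ps.mismatch_positions = tuple(i + 1 for i in range(j))
        ps.mirna_id = f"{mature.id}m{j}"
        out.append(ps)
    return out
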