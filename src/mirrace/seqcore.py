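"""Nucleic-acid sequence primitives shared by every mirrace module.

Sequences are stored as uppercase strings tagged with their alphabet (DNA or
RNA).  Per-position indices in every report produced by this package are
1-based counting from the 5' end, which is the convention used throughout
the miRNA literature ("position 2-8 seed", "cleavage at nucleotide 10").
Internal code may use 0-based offsets, but nothing 0-based ever leaves a
public data structure.

Ambiguity codes (N, R, Y, ...) are tolerated in bulk inputs such as ESTs and
clone reads, where they behave as never-matching symbols; primer and mature
miRNA constructors reject them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Alphabet = Literal["DNA", "RNA"]

_DNA_STRICT = set("ACGT")
_RNA_STRICT = set("ACGU")
# IUPAC ambiguity codes: tolerated, never match anything during comparison.
_AMBIGUOUS = set("NRYSWKMBDHV")


class AlphabetError(ValueError):
    """Raised when residues are not valid nucleotides for the declared alphabet."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over a single declared alphabet.

    Residues are canonicalized to uppercase.  ``strict=True`` (used for
    primers and mature miRNAs) rejects ambiguity codes.
    """

    id: str
    residues: str
    alphabet: Alphabet = "DNA"
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper().replace(" ", ""))
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence for id {self.id!r}")
        core = _DNA_STRICT if self.alphabet == "DNA" else _RNA_STRICT
        allowed = core if self.strict else core | _AMBIGUOUS
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"{self.id!r}: invalid {self.alphabet} symbol(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class PositionDiff:
    """A single substitution between two aligned sequences (1-based from 5')."""

    position: int
    ref_nt: str
    alt_nt: str


def convert_alphabet(seq: NucSequence, target: Alphabet) -> NucSequence:
    """Swap U<->T to move between RNA and DNA; idempotent when already there."""
    if seq.alphabet == target:
        return seq
    if target == "DNA":
        res = seq.residues.replace("U", "T")
    else:
        res = seq.residues.replace("T", "U")
    return NucSequence(seq.id, res, target, strict=seq.strict)


def dna(seq: NucSequence) -> NucSequence:
    return convert_alphabet(seq, "DNA")


def rna(seq: NucSequence) -> NucSequence:
    return convert_alphabet(seq, "RNA")


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Same-alphabet reverse complement; an involution."""
    if seq.alphabet == "DNA":
        rc = str(Seq(seq.residues).reverse_complement())
    else:
        rc = str(Seq(seq.residues).reverse_complement_rna())
    return NucSequence(seq.id, rc, seq.alphabet, strict=seq.strict)


def diff_positions(a: NucSequence, b: NucSequence) -> list[PositionDiff]:
    """Positions (1-based, 5'->3') where ``a`` and ``b`` differ.

    Comparison is alphabet-insensitive (U and T are equivalent).  Unequal
    lengths are compared over the shorter sequence and flagged with a
    warning, mirroring how partially sequenced orthologs are tabulated.
    """
    ra, rb = rna(a).residues, rna(b).residues
    if len(ra) != len(rb):
        warnings.warn(
            f"length mismatch {a.id!r} ({len(ra)}) vs {b.id!r} ({len(rb)}); "
            "comparing over the shorter",
            stacklevel=2,
        )
    n = min(len(ra), len(rb))
    return [
        PositionDiff(i + 1, ra[i], rb[i]) for i in range(n) if ra[i] != rb[i]
    ]


def hamming(a: NucSequence, b: NucSequence) -> int:
    """Substitution count between two sequences (U/T-insensitive)."""
    return len(diff_positions(a, b))


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[NucSequence]:
    """Read a (wrapped or single-line, LF or CRLF) FASTA file.

    ``alphabet=None`` infers per record: any U present -> RNA, else DNA.
    Duplicate ids raise a warning; an empty record is an error.
    """
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        res = str(rec.seq).upper()
        if not res:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r} in {path}", stacklevel=2)
        seen.add(rec.id)
        ab = alphabet or ("RNA" if "U" in res else "DNA")
        out.append(NucSequence(rec.id, res, ab))
    return out


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(records)
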