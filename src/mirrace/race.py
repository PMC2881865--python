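"""Analysis of cloned miR-RACE and RLM-5'RACE product sequences.

A sequenced 5'-RACE clone reads

    [mirRacer5][adaptor remainder GAAA][mature insert][T x >=10]

and a 3'-RACE clone reads

    [adaptor tail GGAGTAGAAA][mature insert][A x >=30][RT-tail complement]

so trimming is a matter of locating the adaptor signature (on either
strand — orientation is auto-detected) and the homopolymer tract, and
returning the intervening insert.  Inserts from many clones are then
anchored on the candidate precursor by exact match of a 17-nt core
(matching the primer-core length) and vote on the mature termini: 5'
clones carry the true 5' end, 3' clones the true 3' end, and the modal
pair defines the consensus mature.  Frequency tables use the notation
``pos(count/total)`` familiar from cloning papers, e.g. ``1(1/16); 10(14/16)``.

RLM-5'RACE cleavage mapping anchors 5'-truncated sense mRNA fragments on
the target transcript, keeps 5' ends within a ~100-nt window centered on
the miRNA complementary site, and reports per-position counts also in
miRNA coordinates: a fragment starting opposite miRNA nucleotide 10
indicates slicing between the target bases paired to miRNA positions 10
and 11 — the canonical plant cleavage register.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .primers import RaceChemistry
from .seqcore import NucSequence, dna, reverse_complement
from .targets import TargetSite

CORE_LEN = 17
MIN_TRACT = 8  # chemistry guarantees >=10; margin for sequencing slippage
WINDOW_HALF = 50  # cleavage window: 50 nt each side of the site midpoint


class UnclassifiableReadError(ValueError):
    """No adaptor signature found on either strand."""


class TrimError(ValueError):
    pass


class AnchorError(ValueError):
    """Insert or fragment cannot be located on the reference sequence."""


@dataclass(frozen=True)
class CloneRead:
    """One sequenced clone of a RACE PCR product (DNA, any orientation)."""

    id: str
    residues: str
    declared_end: str | None = None  # 'five_prime' | 'three_prime' | None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"empty clone read {self.id!r}")

    def as_seq(self) -> NucSequence:
        return NucSequence(self.id, self.residues, "DNA")


@dataclass
class TrimmedInsert:
    read_id: str
    end: str          # 'five_prime' | 'three_prime'
    insert: str       # DNA residues, miRNA-sense
    flipped: bool     # read was reverse-complemented to find the adaptor
    stripped_prefix: str
    stripped_suffix: str


@dataclass
class EndFrequencyTable:
    """Counts of inferred termini keyed by 1-based position."""

    counts: dict[int, int] = field(default_factory=dict)
    total: int = 0

    def add(self, pos: int) -> None:
        self.counts[pos] = self.counts.get(pos, 0) + 1
        self.total += 1

    @property
    def modal_position(self) -> int:
        if not self.counts:
            raise ValueError("empty frequency table")
        # highest count; ties broken by smaller position for determinism
        return min(self.counts, key=lambda p: (-self.counts[p], p))


@dataclass
class Reconstruction:
    consensus: NucSequence        # RNA mature
    mature_span: tuple[int, int]  # 1-based on the precursor
    table5: EndFrequencyTable     # 5' termini, precursor coordinates
    table3: EndFrequencyTable     # 3' termini, precursor coordinates
    excluded: list[str] = field(default_factory=list)  # clone ids


@dataclass
class CleavageProfile:
    target_id: str
    site_start: int
    site_end: int
    window: tuple[int, int]                     # transcript coords, inclusive
    counts: dict[int, int] = field(default_factory=dict)  # transcript 5'-end pos
    total: int = 0
    off_window: int = 0
    unmapped: list[str] = field(default_factory=list)

    def mirna_position(self, transcript_pos: int) -> int:
        """miRNA nucleotide opposite a transcript position within the site."""
        return self.site_end - transcript_pos + 1

    def mirna_counts(self) -> dict[int, int]:
        return {self.mirna_position(p): c for p, c in sorted(self.counts.items())}

    @property
    def modal_mirna_position(self) -> int:
        t = EndFrequencyTable(dict(self.mirna_counts()), self.total)
        return t.modal_position


def _tract_boundary(seq: str, base: str, search_from: int, exact_len: int) -> int | None:
    """Index where the primer-derived homopolymer tract begins.

    The chemistry contributes an exact tract length (10 T from GSP1, 30 A
    from the anchored oligo-dT), so when the insert itself ends in the same
    base the run exceeds that length and the excess belongs to the insert.
    Runs shorter than ``exact_len`` (sequencing slippage) are accepted whole
    down to MIN_TRACT.
    """
    m = re.search("%s{%d,}" % (base, MIN_TRACT), seq[search_from:])
    if m is None:
        return None
    run_start = search_from + m.start()
    run_end = search_from + m.end()
    return max(run_start, run_end - exact_len)


def trim_clone_read(read: CloneRead, chem: RaceChemistry | None = None) -> TrimmedInsert:
    """Strip the RACE chemistry from a clone read and return the insert.

    Orientation is detected by searching for the adaptor signature on the
    read and on its reverse complement.  The 5'-clone signature
    (mirRacer5 + GAAA) is checked before the 3'-clone signature because the
    latter (GGAGTAGAAA) is its suffix.  ``declared_end``, when present,
    restricts the classification.
    """
    chem = chem or RaceChemistry()
    sig5 = chem.mirracer5 + chem.adaptor5_dna[-chem.adaptor_remainder :]
    sig3 = chem.adaptor_tail

    for flipped in (False, True):
        seq = (
            read.residues
            if not flipped
            else reverse_complement(NucSequence(read.id, read.residues, "DNA")).residues
        )
        if read.declared_end != "three_prime" and sig5 in seq:
            start = seq.index(sig5) + len(sig5)
            t0 = _tract_boundary(seq, "T", start, chem.polyT_len)
            if t0 is None:
                raise TrimError(f"{read.id!r}: no poly-T tract after the 5' adaptor")
            insert = seq[start:t0]
            if not insert:
                raise TrimError(f"{read.id!r}: empty insert")
            return TrimmedInsert(
                read.id, "five_prime", insert, flipped, seq[:start], seq[t0:]
            )
        if read.declared_end != "five_prime" and sig3 in seq:
            start = seq.index(sig3) + len(sig3)
            a0 = _tract_boundary(seq, "A", start, chem.dT_len)
            if a0 is None:
                raise TrimError(f"{read.id!r}: no poly-A tract after the adaptor tail")
            insert = seq[start:a0]
            if not insert:
                raise TrimError(f"{read.id!r}: empty insert")
            return TrimmedInsert(
                read.id, "three_prime", insert, flipped, seq[:start], seq[a0:]
            )
    raise UnclassifiableReadError(f"{read.id!r}: no adaptor signature found")


def _anchor(insert: str, precursor_dna: str, end: str) -> tuple[int, int]:
    """Locate an insert on the precursor via its inner 17-nt core.

    Returns the (five_prime, three_prime) 1-based terminus positions the
    insert implies.  5' clones carry a trustworthy 5' end and a
    primer-determined 3' end, and vice versa, so the core used for
    anchoring is the primer-side half.
    """
    if len(insert) < CORE_LEN:
        raise AnchorError(f"insert shorter than the {CORE_LEN}-nt core")
    core = insert[-CORE_LEN:] if end == "five_prime" else insert[:CORE_LEN]
    idx = precursor_dna.find(core)
    if idx < 0:
        raise AnchorError("core not found in precursor (cross-contamination?)")
    if end == "five_prime":
        p3 = idx + CORE_LEN          # 1-based position of insert 3' end
        p5 = p3 - len(insert) + 1
    else:
        p5 = idx + 1
        p3 = p5 + len(insert) - 1
    if p5 < 1 or p3 > len(precursor_dna):
        raise AnchorError("insert extends beyond the precursor")
    return p5, p3


def reconstruct_mature(
    clones5: list[CloneRead],
    clones3: list[CloneRead],
    precursor: NucSequence,
    chem: RaceChemistry | None = None,
) -> Reconstruction:
    """Vote 5'/3' termini from trimmed clones and splice the consensus mature."""
    if not clones5 or not clones3:
        raise ValueError("need at least one clone per end")
    chem = chem or RaceChemistry()
    prec = dna(precursor).residues
    t5, t3 = EndFrequencyTable(), EndFrequencyTable()
    excluded: list[str] = []
    for clones, table, end in ((clones5, t5, "five_prime"), (clones3, t3, "three_prime")):
        for read in clones:
            try:
                ins = trim_clone_read(read, chem)
                p5, p3 = _anchor(ins.insert, prec, ins.end)
            except (UnclassifiableReadError, TrimError, AnchorError):
                excluded.append(read.id)
                continue
            table.add(p5 if end == "five_prime" else p3)
    if t5.total == 0 or t3.total == 0:
        raise ValueError("no anchorable clone for one of the ends")
    s, e = t5.modal_position, t3.modal_position
    consensus = NucSequence(
        f"{precursor.id}_mature", prec[s - 1 : e].replace("T", "U"), "RNA"
    )
    return Reconstruction(consensus, (s, e), t5, t3, excluded)


def format_frequency(t: EndFrequencyTable) -> str:
    """Render ``pos(count/total)`` entries sorted by position, '; '-joined."""
    if t.total <= 0:
        raise ValueError("empty frequency table")
    return "; ".join(f"{p}({t.counts[p]}/{t.total})" for p in sorted(t.counts))


def parse_frequency(text: str) -> EndFrequencyTable:
    """Inverse of :func:`format_frequency` (accepts the spacing variants of
    published tables)."""
    counts: dict[int, int] = {}
    total = 0
    for part in filter(None, (p.strip() for p in text.split(";"))):
        m = re.fullmatch(r"(\d+)\((\d+)/(\d+)\)", part)
        if m is None:
            raise ValueError(f"unparseable frequency entry {part!r}")
        counts[int(m.group(1))] = counts.get(int(m.group(1)), 0) + int(m.group(2))
        total = int(m.group(3))
    return EndFrequencyTable(counts, total)


def map_cleavage_sites(
    fragments: list[CloneRead],
    transcript: NucSequence,
    site: TargetSite | tuple[int, int],
    anchor_len: int = 20,
) -> CleavageProfile:
    """Locate fragment 5' ends on the transcript around a miRNA site.

    ``site`` may be a :class:`TargetSite` or a raw (start, end) pair.
    Fragments are 5'-truncated sense copies; each is anchored by exact
    prefix match.  Ends outside the window (site midpoint +/- 50 nt) are
    tallied separately; unmappable fragments are excluded and listed.
    """
    if isinstance(site, tuple):
        s_start, s_end = site
        target_id = transcript.id
    else:
        s_start, s_end = site.start, site.end
        target_id = site.transcript_id
    tr = dna(transcript).residues
    if not 1 <= s_start <= s_end <= len(tr):
        raise ValueError("site does not lie on the transcript")
    mid = (s_start + s_end) // 2
    lo, hi = max(1, mid - WINDOW_HALF), min(len(tr), mid + WINDOW_HALF)
    profile = CleavageProfile(
        target_id=target_id,
        site_start=s_start,
        site_end=s_end,
        window=(lo, hi),
    )
    for frag in fragments:
        prefix = dna(frag.as_seq()).residues[:anchor_len]
        idx = tr.find(prefix)
        if idx < 0 or len(prefix) < min(anchor_len, 12):
            profile.unmapped.append(frag.id)
            continue
        p = idx + 1
        if lo <= p <= hi:
            profile.counts[p] = profile.counts.get(p, 0) + 1
            profile.total += 1
        else:
            profile.off_window += 1
    return profile


def format_cleavage(profile: CleavageProfile) -> str:
    """Cleavage profile in miRNA coordinates, Table-style ``pos(count/total)``."""
    if profile.total == 0:
        return ""
    mc = profile.mirna_counts()
    return "; ".join(
        f"{p}({mc[p]}/{profile.total})" for p in sorted(mc)
    )
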