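"""Seed-anchored homology scan of ESTs against known mature miRNAs.

The prediction pipeline mirrors classical EST-based plant miRNA searches:
take each known mature miRNA, align its seed (positions 2-8 from the 5' end)
to the ESTs on both strands, extract a same-length "raw miRNA" at every seed
hit, discard raw miRNAs with more than three mismatches outside the seed
(position 1 is treated as non-seed: only positions 2-8 are protected), fold
flanking windows of EST context, and keep candidates whose best window
passes all six hairpin criteria.

All reported coordinates are 1-based on the forward strand; minus-strand
hits carry a strand tag and their extracted sequence is from the reverse
complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hairpin import (
    CriteriaReport,
    HairpinConfig,
    HairpinStructure,
    Span,
    evaluate_criteria,
    fold_hairpin,
)
from .seqcore import NucSequence, reverse_complement, rna


@dataclass(frozen=True)
class MatureMiRNA:
    """A known mature miRNA (RNA-canonical) with its positional seed."""

    id: str
    sequence: NucSequence

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", rna(self.sequence))
        L = len(self.sequence)
        if not 18 <= L <= 26:
            raise ValueError(f"{self.id!r}: mature length {L} outside 18..26")

    @property
    def seed(self) -> str:
        """Positions 2-8 inclusive (7 nt)."""
        return self.sequence.residues[1:8]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RawHit:
    """A seed-anchored window extracted from an EST (forward-strand coords)."""

    est_id: str
    strand: str  # '+' | '-'
    start: int   # 1-based, leftmost base of the hit region on forward strand
    extracted: NucSequence  # RNA, same length as the known miRNA
    nonseed_mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based on the miRNA


@dataclass
class PredictConfig:
    max_nonseed_mm: int = 3
    max_subs_vs_known: int = 4
    window_extents: tuple[int, ...] = (60, 100, 150)
    both_strands: bool = True
    hairpin: HairpinConfig = field(default_factory=HairpinConfig)


@dataclass
class CandidateWindow:
    precursor: NucSequence  # RNA, on the hit strand
    mature: Span            # mature span within the window
    extent: int
    truncated: bool


@dataclass
class Candidate:
    """A pipeline prediction: a raw hit whose best window passes all criteria."""

    known_id: str
    est_id: str
    strand: str
    start: int
    mature: str  # RNA residues
    substitutions: int
    report: CriteriaReport
    structure: HairpinStructure
    window: CandidateWindow


def _scan_one_strand(
    known: MatureMiRNA, strand_seq: str, est_id: str, strand: str, fwd_len: int
) -> list[RawHit]:
    L = len(known)
    kres = known.sequence.residues
    seed = known.seed
    hits = []
    for off in range(len(strand_seq) - L + 1):
        window = strand_seq[off : off + L]
        if window[1:8] != seed:
            continue
        mm = tuple(
            i + 1
            for i in range(L)
            if not 1 <= i <= 7 and window[i] != kres[i]
        )
        start_fwd = off + 1 if strand == "+" else fwd_len - (off + L) + 1
        hits.append(
            RawHit(
                est_id=est_id,
                strand=strand,
                start=start_fwd,
                extracted=NucSequence(f"{est_id}:{start_fwd}{strand}", window, "RNA"),
                nonseed_mismatches=len(mm),
                mismatch_positions=mm,
            )
        )
    return hits


def seed_scan(
    known: MatureMiRNA, est: NucSequence, both_strands: bool = True
) -> list[RawHit]:
    """All windows of the EST whose positions 2-8 exactly match the seed."""
    if len(est) < len(known):
        return []
    fwd = rna(est).residues
    hits = _scan_one_strand(known, fwd, est.id, "+", len(est))
    if both_strands:
        rev = rna(reverse_complement(est)).residues
        hits += _scan_one_strand(known, rev, est.id, "-", len(est))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def pattern_filter(
    hits: list[RawHit], known: MatureMiRNA, cfg: PredictConfig | None = None
) -> list[RawHit]:
    """Keep hits with <= max_nonseed_mm mismatches, all outside the seed."""
    cfg = cfg or PredictConfig()
    for h in hits:
        if len(h.extracted) != len(known):
            raise ValueError(
                f"hit length {len(h.extracted)} != known length {len(known)}"
            )
    return [h for h in hits if h.nonseed_mismatches <= cfg.max_nonseed_mm]


def extract_precursor_windows(
    est: NucSequence, hit: RawHit, cfg: PredictConfig | None = None
) -> list[CandidateWindow]:
    """Flanking windows around the hit on the hit's strand, one per extent."""
    cfg = cfg or PredictConfig()
    L = len(hit.extracted)
    n = len(est)
    strand_seq = rna(est if hit.strand == "+" else reverse_complement(est)).residues
    off = hit.start - 1 if hit.strand == "+" else n - (hit.start - 1) - L
    out = []
    for ext in cfg.window_extents:
        lo = max(0, off - ext)
        hi = min(n, off + L + ext)
        truncated = lo > off - ext or hi < off + L + ext
        window = strand_seq[lo:hi]
        mature = Span(off - lo + 1, off - lo + L)
        out.append(
            CandidateWindow(
                precursor=NucSequence(
                    f"{est.id}:{hit.start}{hit.strand}:w{ext}", window, "RNA"
                ),
                mature=mature,
                extent=ext,
                truncated=truncated,
            )
        )
    return out


def predict_mirnas(
    known_set: list[MatureMiRNA],
    est_set: list[NucSequence],
    cfg: PredictConfig | None = None,
) -> list[Candidate]:
    """Full pipeline: scan -> filter -> window -> fold -> criteria.

    Emits one candidate per (hit) whose best-scoring window passes all six
    criteria; identical mature sequences are deduplicated (first in the
    deterministic (est_id, start, strand) order wins).
    """
    cfg = cfg or PredictConfig()
    candidates: list[Candidate] = []
    for known in known_set:
        for est in est_set:
            hits = pattern_filter(
                seed_scan(known, est, cfg.both_strands), known, cfg
            )
            for hit in hits:
                best: tuple[HairpinStructure, CriteriaReport, CandidateWindow] | None = None
                for win in extract_precursor_windows(est, hit, cfg):
                    if len(win.precursor) < cfg.hairpin.min_precursor_len:
                        continue
                    h = fold_hairpin(win.precursor, win.mature)
                    rep = evaluate_criteria(
                        h, win.mature, known.sequence, cfg.hairpin
                    )
                    if rep.passed and (
                        best is None or h.fold_score < best[0].fold_score
                    ):
                        best = (h, rep, win)
                if best is not None:
                    h, rep, win = best
                    candidates.append(
                        Candidate(
                            known_id=known.id,
                            est_id=est.id,
                            strand=hit.strand,
                            start=hit.start,
                            mature=hit.extracted.residues,
                            substitutions=hit.nonseed_mismatches,
                            report=rep,
                            structure=h,
                            window=win,
                        )
                    )
    candidates.sort(key=lambda c: (c.est_id, c.start, c.strand))
    seen: set[str] = set()
    unique = []
    for c in candidates:
        if c.mature not in seen:
            seen.add(c.mature)
            unique.append(c)
    return unique
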