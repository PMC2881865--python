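"""Ungapped miRNA:mRNA duplex evaluation with position-specific mismatch rules.

Plant miRNAs direct cleavage of near-perfectly complementary mRNA sites, so
target prediction can be phrased as sliding an ungapped window over each
transcript and classifying every miRNA position (1..L from the miRNA 5'
end) against the base opposite it: Watson-Crick (A:U, G:C), G:U wobble, or
mismatch.  The default rule set caps mismatches by region:

* at most 1 in positions 1-9,
* none at the cleavage site (positions 10 and 11),
* at most 2 from position 12 through the miRNA 3' end,
* no more than 4 in total, no run of more than 2 consecutive mismatches,
  and no gaps.

G:U wobbles count as full mismatches by default (``wobble_weight=1.0``,
configurable to 0.5; weighted sums are rounded half-up before comparison
with the integer caps).  An alternate preset encodes the Schwab-style rules
(one mismatch in positions 2-12 instead of 1-9, three allowed after 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqcore import NucSequence, rna

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

PATTERN_CHARS = {"WC": "|", "wobble": "o", "mismatch": "x"}


@dataclass
class TargetRuleConfig:
    """Region caps are (start, end, max_weighted_mismatches); end=None = miRNA 3' end."""

    regions: tuple[tuple[int, int | None, int], ...] = (
        (1, 9, 1),
        (10, 11, 0),
        (12, None, 2),
    )
    max_total: int = 4
    max_consecutive: int = 2
    gaps_allowed: bool = False  # fixed; documented for completeness
    wobble_weight: float = 1.0

    @classmethod
    def paper_rules(cls) -> "TargetRuleConfig":
        return cls()

    @classmethod
    def schwab(cls) -> "TargetRuleConfig":
        return cls(regions=((2, 12, 1), (10, 11, 0), (12, None, 3)))


@dataclass
class DuplexAlignment:
    """Per-position pairing classes of a miRNA against a sense target site."""

    mirna_id: str
    mirna: str   # RNA residues, 5'->3'
    site: str    # RNA residues, transcript sense, 5'->3'
    classes: tuple[str, ...]  # per miRNA position 1..L: WC|wobble|mismatch

    @property
    def pattern(self) -> str:
        return "".join(PATTERN_CHARS[c] for c in self.classes)

    def positions(self, cls_name: str) -> list[int]:
        return [i + 1 for i, c in enumerate(self.classes) if c == cls_name]

    @property
    def n_wobbles(self) -> int:
        return len(self.positions("wobble"))

    @property
    def n_mismatches(self) -> int:
        return len(self.positions("mismatch"))


@dataclass
class RuleVerdict:
    accept: bool
    region_counts: dict[str, float]
    total: float
    max_run: int
    reasons: list[str] = field(default_factory=list)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based transcript-sense coordinates, inclusive
    end: int
    alignment: DuplexAlignment
    verdict: RuleVerdict


def align_duplex(mirna: NucSequence, site: NucSequence) -> DuplexAlignment:
    """Classify each miRNA position against the sense site read 3'->5'.

    miRNA position i (1-based from its 5' end) faces site position L-i+1,
    because the duplex is antiparallel.  Ambiguity codes never pair.
    """
    m = rna(mirna).residues
    s = rna(site).residues
    if len(m) != len(s):
        raise ValueError(f"length mismatch: miRNA {len(m)} vs site {len(s)}")
    L = len(m)
    classes = []
    for i in range(L):
        pair = (m[i], s[L - 1 - i])
        if pair in _WC:
            classes.append("WC")
        elif pair in _WOBBLE:
            classes.append("wobble")
        else:
            classes.append("mismatch")
    return DuplexAlignment(mirna.id, m, s, tuple(classes))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def apply_target_rules(
    d: DuplexAlignment, cfg: TargetRuleConfig | None = None
) -> RuleVerdict:
    """Accept/reject a duplex under the region caps, total cap, and run cap."""
    cfg = cfg or TargetRuleConfig()
    L = len(d.classes)
    weight = {
        "WC": 0.0,
        "wobble": cfg.wobble_weight,
        "mismatch": 1.0,
    }
    w = [weight[c] for c in d.classes]

    reasons = []
    region_counts: dict[str, float] = {}
    for start, end, cap in cfg.regions:
        stop = L if end is None else min(end, L)
        count = sum(w[start - 1 : stop])
        label = f"{start}-{end or L}"
        region_counts[label] = count
        if _round_half_up(count) > cap:
            reasons.append(f"region {label}: {count:g} > {cap}")

    total = sum(w)
    if _round_half_up(total) > cfg.max_total:
        reasons.append(f"total {total:g} > {cfg.max_total}")

    # consecutive-mismatch runs: positions that count as full mismatches
    run = max_run = 0
    for i, c in enumerate(d.classes):
        if w[i] >= 1.0:
            run += 1
            max_run = max(max_run, run)
        else:
            run = 0
    if max_run > cfg.max_consecutive:
        reasons.append(f"{max_run} consecutive mismatches > {cfg.max_consecutive}")

    return RuleVerdict(
        accept=not reasons,
        region_counts=region_counts,
        total=total,
        max_run=max_run,
        reasons=reasons,
    )


def scan_targets(
    mirna: NucSequence,
    transcripts: list[NucSequence],
    cfg: TargetRuleConfig | None = None,
) -> list[TargetSite]:
    """Evaluate every length-L sense window of each transcript.

    The window itself is the reported site; its reverse-complement relation
    to the miRNA is what :func:`align_duplex` classifies.  Coordinates are
    transcript-sense, 1-based, in deterministic (transcript, start) order.
    """
    cfg = cfg or TargetRuleConfig()
    m = rna(mirna)
    L = len(m)
    out = []
    for tr in transcripts:
        seq = rna(tr)
        for off in range(len(seq) - L + 1):
            site = NucSequence(
                f"{tr.id}:{off + 1}", seq.residues[off : off + L], "RNA"
            )
            aln = align_duplex(m, site)
            verdict = apply_target_rules(aln, cfg)
            if verdict.accept:
                out.append(
                    TargetSite(
                        mirna_id=mirna.id,
                        transcript_id=tr.id,
                        start=off + 1,
                        end=off + L,
                        alignment=aln,
                        verdict=verdict,
                    )
                )
    return out
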