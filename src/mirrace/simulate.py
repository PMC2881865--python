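"""Deterministic synthetic-data generators with recorded ground truth.

Every generator takes an integer seed and reproduces byte-identical output
for the same seed, so the whole pipeline is testable without any external
download.  The generators emulate the input classes the method consumes:

* ``make_precursor`` — a stem-loop [5' pad][mature][loop][star][3' pad]
  whose star carries exactly ``k`` engineered non-pairing positions, so the
  default folding model recovers ``duplex_mismatches == k``;
* ``make_est`` — EST-sized uniform-background sequences with hairpins
  implanted at recorded offsets/strands, plus dinucleotide-shuffled decoys
  (composition preserved, structure destroyed);
* ``simulate_race_clones`` — RACE clone reads built per the amplicon
  structure with categorical terminal-nucleotide noise over offsets -2..+2;
* ``simulate_degradome_clones`` — 5'-truncated sense mRNA fragments
  concentrated at a programmed cut position (canonically opposite miRNA
  nucleotide 10).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any

from .hairpin import Span, duplex_mismatch_count, evaluate_criteria, fold_hairpin
from .primers import RaceChemistry
from .race import CloneRead
from .seqcore import NucSequence, dna, reverse_complement, rna

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
# bases that can pair X under the WC+wobble model
_PARTNERS = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}


class GeometryError(ValueError):
    """Requested precursor geometry cannot be realized."""


@dataclass
class FixtureTruth:
    """Ground truth recorded by a generator; regenerable from the seed."""

    seed: int
    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"seed": self.seed, "kind": self.kind, **self.params}


def random_mature(length: int = 21, seed: int = 0) -> NucSequence:
    """A random RNA mature starting with U (the canonical plant 5' base).

    Homopolymer runs are capped at 3 nt — long runs are rare in real mature
    miRNAs and make stem registers degenerate.
    """
    rng = random.Random(seed)
    res = ["U"]
    while len(res) < length:
        b = rng.choice("ACGU")
        if len(res) >= 3 and res[-1] == res[-2] == res[-3] == b:
            continue
        res.append(b)
    return NucSequence(f"synt-mir-{seed}", "".join(res), "RNA")


def mutate_nonseed(
    mature: NucSequence, n_subs: int, seed: int = 0
) -> NucSequence:
    """Substitute ``n_subs`` positions outside the seed (2-8), seeded."""
    rng = random.Random(seed)
    res = list(rna(mature).residues)
    eligible = [i for i in range(len(res)) if not 1 <= i <= 7]
    for i in rng.sample(eligible, n_subs):
        res[i] = rng.choice([b for b in "ACGU" if b != res[i]])
    return NucSequence(f"{mature.id}_sub{n_subs}", "".join(res), "RNA")


_PAIR_W = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def _w(a: str, b: str) -> int:
    return _PAIR_W.get((a, b), 0)


def _wc_weight(b: str) -> int:
    """Weight of b paired with its Watson-Crick complement."""
    return 3 if b in "GC" else 2


def _inert_fill_base(n1: str, n2: str, wd: int) -> str:
    """A filler base whose pairing with the two duplex-terminal bases
    ``n1``/``n2`` is strictly weaker than the duplex pair it would displace
    (weight ``wd``), so the folder provably never recruits filler into the
    mature:star duplex.  Such a base always exists."""
    for b in "CUGA":
        if _w(b, n1) < wd and _w(b, n2) < wd:
            return b
    raise AssertionError("no inert filler base")  # pragma: no cover


def _single_bases(m: str, i: int) -> list[str]:
    """Engineered star residues safe opposite an isolated mature index i.

    A safe base pairs the opposite mature base not at all, and pairs each
    mature neighbor strictly weaker than that neighbor's own duplex pair —
    so recruiting it into any alternative pairing is always score-losing.
    """
    return [
        b
        for b in "ACGU"
        if _w(b, m[i]) == 0
        and _w(b, m[i - 1]) < _wc_weight(m[i - 1])
        and _w(b, m[i + 1]) < _wc_weight(m[i + 1])
    ]


def _single_safe(m: str, i: int) -> bool:
    """Unpaired mature base at i cannot profitably re-pair with the star
    residues opposite its neighbors (no register slide)."""
    return (
        _w(m[i], _COMPLEMENT[m[i - 1]]) < _wc_weight(m[i - 1])
        and _w(m[i], _COMPLEMENT[m[i + 1]]) < _wc_weight(m[i + 1])
    )


def _pair_bases(m: str, i: int) -> list[str]:
    """Engineered star residues safe opposite either half of an adjacent
    mismatch block (i, i+1): must pair neither unpaired mature base and be
    strictly weaker than the flanking duplex pairs they could displace."""
    return [
        b
        for b in "ACGU"
        if _w(b, m[i]) == 0
        and _w(b, m[i + 1]) == 0
        and _w(b, m[i - 1]) < _wc_weight(m[i - 1])
        and _w(b, m[i + 2]) < _wc_weight(m[i + 2])
    ]


def _pair_safe(m: str, i: int) -> bool:
    """Register safety for an adjacent block (i, i+1): neither unpaired
    mature base may profitably reach the star residues opposite the block's
    flanks (each such pairing displaces only one duplex pair)."""
    wd_l, wd_r = _wc_weight(m[i - 1]), _wc_weight(m[i + 2])
    cl, cr = _COMPLEMENT[m[i - 1]], _COMPLEMENT[m[i + 2]]
    return (
        _w(m[i], cl) < wd_l
        and _w(m[i], cr) < wd_r
        and _w(m[i + 1], cl) < wd_l
        and _w(m[i + 1], cr) < wd_r
    )


def _plan_mismatches(
    m: str, k: int, rng: random.Random
) -> dict[int, str]:
    """Choose engineered mismatch positions (0-based mature indices) and
    their star substitutions: blocks of one or two adjacent positions,
    block edges separated by at least two paired positions, all interior.

    Blocks of two keep the unpaired stretches within the hairpin filter's
    break tolerance; wider blocks never occur.  Raises GeometryError when
    the mature sequence cannot host ``k`` safe mismatches.
    """
    if k == 0:
        return {}
    L = len(m)
    singles = [
        (i,) for i in range(2, L - 2) if _single_safe(m, i) and _single_bases(m, i)
    ]
    pairs = [
        (i, i + 1)
        for i in range(2, L - 3)
        if _pair_safe(m, i) and _pair_bases(m, i)
    ]
    blocks = singles + pairs

    def cross_ok(pos: int, b: str, plan: dict[int, str]) -> bool:
        # engineered positions two apart share one paired position between
        # them; neither unpaired mature base may reach the other's star
        # residue at a profit (each such pairing displaces only that one
        # duplex pair)
        for a in (pos - 2, pos + 2):
            if a in plan:
                mid = (pos + a) // 2
                if mid in plan:
                    continue  # same block, handled by the pair constraints
                wd_mid = _wc_weight(m[mid])
                if _w(m[a], b) >= wd_mid or _w(m[pos], plan[a]) >= wd_mid:
                    return False
        return True

    for _ in range(400):
        rng.shuffle(blocks)
        chosen: list[tuple[int, ...]] = []
        total = 0
        for blk in blocks:
            if total + len(blk) > k:
                continue
            if all(
                min(abs(a - b) for a in blk for b in other) >= 2
                for other in chosen
            ):
                chosen.append(blk)
                total += len(blk)
            if total == k:
                break
        if total != k:
            continue
        plan: dict[int, str] = {}
        feasible = True
        for blk in sorted(chosen):
            opts = _single_bases(m, blk[0]) if len(blk) == 1 else _pair_bases(m, blk[0])
            for pos in blk:
                cands = [b for b in opts if cross_ok(pos, b, plan)]
                if not cands:
                    feasible = False
                    break
                plan[pos] = rng.choice(cands)
            if not feasible:
                break
        if feasible:
            return plan
    raise GeometryError(f"cannot place {k} register-safe mismatches on a {L}-mer")


def _engineer_star(mature_res: str, plan: dict[int, str]) -> str:
    """revcomp(mature) with the planned substitutions opposite each
    engineered mature index."""
    L = len(mature_res)
    star = [
        _COMPLEMENT[b] for b in reversed(mature_res)
    ]  # star index L-1-i faces mature i
    for i, b in plan.items():
        star[L - 1 - i] = b
    return "".join(star)


def make_precursor(
    mature: NucSequence,
    star_mismatches: int = 0,
    loop_len: int = 6,
    seed: int = 0,
    pad_len: int = 8,
) -> tuple[NucSequence, FixtureTruth]:
    """Build [pad][mature][loop][star][pad] with exactly ``star_mismatches``
    engineered duplex mismatches, verified against the default folding model.
    """
    k = star_mismatches
    if k > 8:
        raise GeometryError("at most 8 engineered mismatches supported")
    if loop_len < 3:
        raise GeometryError("loop must be at least 3 nt")
    m = rna(mature).residues
    L = len(m)
    rng = random.Random(seed)
    # filler must not displace the duplex pairs at the mature 5' end (pad5),
    # the mature 3' end (loop), or the star 3' end (pad3)
    pad5_b = _inert_fill_base(m[0], m[1], _wc_weight(m[0]))
    loop_b = _inert_fill_base(m[-1], m[-2], _wc_weight(m[-1]))
    pad5 = pad5_b * pad_len
    pad3 = pad5_b * pad_len
    loop = loop_b * loop_len
    for attempt in range(40):
        plan = _plan_mismatches(m, k, rng)
        positions = sorted(plan)
        star = _engineer_star(m, plan)
        res = pad5 + m + loop + star + pad3
        prec = NucSequence(f"{mature.id}_prec_k{k}_s{seed}", res, "RNA")
        span = Span(pad_len + 1, pad_len + L)
        h = fold_hairpin(prec, span)
        star_lo, star_hi = pad_len + L + loop_len + 1, pad_len + L + loop_len + L
        partners = [
            h.pair_table[p - 1]
            for p in range(span.start, span.end + 1)
            if h.pair_table[p - 1] != 0
        ]
        unpaired = [
            p - span.start
            for p in range(span.start, span.end + 1)
            if h.pair_table[p - 1] == 0
        ]
        rep = evaluate_criteria(h, span)
        geometry_ok = partners and all(star_lo <= q <= star_hi for q in partners)
        if k <= 6:
            # precursors inside the filter's tolerance must cleanly pass the
            # structural criteria with exactly the engineered mismatches
            geometry_ok = (
                geometry_ok
                and unpaired == positions
                and rep.criteria[3] and rep.criteria[4] and rep.criteria[5]
            )
        if geometry_ok and duplex_mismatch_count(h, span) == k:
            truth = FixtureTruth(
                seed=seed,
                kind="precursor",
                params={
                    "mature": m,
                    "mature_span": (span.start, span.end),
                    "star_span": (pad_len + L + loop_len + 1, pad_len + L + loop_len + L),
                    "engineered_mismatches": k,
                    "mismatch_positions_1based": [p + 1 for p in positions],
                    "attempt": attempt,
                },
            )
            return prec, truth
    raise GeometryError(
        f"could not realize {k} duplex mismatches for {mature.id!r} (seed {seed})"
    )


def draw_feasible_precursor(
    star_mismatches: int,
    length: int = 21,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[NucSequence, NucSequence, FixtureTruth]:
    """First (mature, precursor, truth) in the seed stream that can host the
    requested mismatch count.

    Not every random mature can geometrically accommodate ``k`` engineered
    duplex mismatches; this advances the seed until one can (deterministic
    rejection sampling), which is how batches of study precursors are drawn.
    """
    for t in range(max_tries):
        s = seed + t
        mat = random_mature(length, seed=s)
        try:
            prec, truth = make_precursor(mat, star_mismatches, seed=s)
        except GeometryError:
            continue
        return mat, prec, truth
    raise GeometryError(
        f"no feasible mature found for k={star_mismatches} in {max_tries} draws"
    )


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick a random last edge per vertex (except the terminal vertex) that
    # forms a tree toward ``last``; rejection-sample for connectivity
    for _ in range(500):
        lasts = {}
        ok = True
        for v, out in edges.items():
            if v == last:
                continue
            lasts[v] = rng.choice(out)
        # check every vertex reaches `last` through the chosen last-edges
        for v in edges:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in lasts:
                    ok = False
                    break
                seen.add(cur)
                cur = lasts[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection practically always succeeds
        return "".join(rng.sample(seq, len(seq)))
    out_lists = {}
    for v, out in edges.items():
        rest = list(out)
        if v in lasts:
            rest.remove(lasts[v])
        rng.shuffle(rest)
        if v in lasts:
            rest.append(lasts[v])
        out_lists[v] = rest
    walk = [seq[0]]
    cur = seq[0]
    while out_lists.get(cur):
        nxt = out_lists[cur].pop(0)
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def make_est(
    precursors: list[NucSequence],
    n_decoys: int = 0,
    est_len: int = 400,
    seed: int = 0,
) -> tuple[list[NucSequence], FixtureTruth]:
    """Implant each precursor (random offset/strand) in uniform background;
    add ESTs carrying dinucleotide-shuffled decoys."""
    rng = random.Random(seed)
    ests: list[NucSequence] = []
    implants = []
    for i, prec in enumerate(precursors):
        p = dna(prec).residues
        if est_len < len(p) + 40:
            raise ValueError("est_len too short for the precursor")
        strand = rng.choice("+-")
        ins = (
            p
            if strand == "+"
            else reverse_complement(NucSequence("p", p, "DNA")).residues
        )
        offset = rng.randrange(0, est_len - len(ins) + 1)
        bg = "".join(rng.choice("ACGT") for _ in range(est_len - len(ins)))
        res = bg[:offset] + ins + bg[offset:]
        est = NucSequence(f"est_implant_{i}", res, "DNA")
        ests.append(est)
        implants.append(
            {"est_id": est.id, "precursor_id": prec.id, "offset": offset + 1,
             "strand": strand}
        )
    for d in range(n_decoys):
        src = dna(precursors[d % len(precursors)]).residues if precursors else None
        shuf = dinucleotide_shuffle(src, rng) if src else ""
        bg = "".join(rng.choice("ACGT") for _ in range(est_len - len(shuf)))
        offset = rng.randrange(0, est_len - len(shuf) + 1) if shuf else 0
        res = bg[:offset] + shuf + bg[offset:]
        ests.append(NucSequence(f"est_decoy_{d}", res, "DNA"))
    truth = FixtureTruth(
        seed=seed,
        kind="est",
        params={"implants": implants, "n_decoys": n_decoys, "est_len": est_len},
    )
    return ests, truth


def _sample_offsets(
    end_noise: dict[int, float], n: int, rng: random.Random
) -> list[int]:
    offsets = sorted(end_noise)
    weights = [end_noise[o] for o in offsets]
    return rng.choices(offsets, weights=weights, k=n)


def simulate_race_clones(
    mature: NucSequence,
    precursor: NucSequence,
    chem: RaceChemistry | None = None,
    end_noise: dict[int, float] | None = None,
    n: int = 16,
    seed: int = 0,
    end: str = "five_prime",
) -> tuple[list[CloneRead], FixtureTruth]:
    """Clone reads per the amplicon structure, with terminus noise.

    ``end_noise`` is a categorical distribution over offsets -2..+2 applied
    to the terminus under test (5' start for 5' clones, 3' end for 3'
    clones); offset 0 with probability 1 by default.
    """
    if n < 1:
        raise ValueError("need n >= 1 clones")
    chem = chem or RaceChemistry()
    end_noise = end_noise or {0: 1.0}
    rng = random.Random(seed)
    prec = dna(precursor).residues
    mat = dna(mature).residues
    idx = prec.find(mat)
    if idx < 0:
        raise ValueError("mature not found in precursor")
    s, e = idx + 1, idx + len(mat)  # 1-based mature span on the precursor
    offsets = _sample_offsets(end_noise, n, rng)
    reads = []
    realized = []
    for i, off in enumerate(offsets):
        if end == "five_prime":
            p5 = min(max(1, s + off), e - CORE_MIN + 1)
            insert = prec[p5 - 1 : e]
            res = (
                chem.mirracer5
                + chem.adaptor5_dna[-chem.adaptor_remainder :]
                + insert
                + "T" * chem.polyT_len
            )
            realized.append(p5)
        else:
            p3 = max(min(len(prec), e + off), s + CORE_MIN - 1)
            insert = prec[s - 1 : p3]
            res = (
                chem.adaptor_tail
                + insert
                + "A" * chem.dT_len
                + reverse_complement(
                    NucSequence("rt", chem.mirracer3, "DNA")
                ).residues
            )
            realized.append(p3)
        reads.append(
            CloneRead(
                id=f"{mature.id}_{end}_clone{i}",
                residues=res,
                declared_end=end,
                source="simulated",
            )
        )
    truth = FixtureTruth(
        seed=seed,
        kind="race_clones",
        params={
            "end": end,
            "mature_span": (s, e),
            "programmed_noise": end_noise,
            "realized_termini": realized,
        },
    )
    return reads, truth


CORE_MIN = 17  # inserts must retain the anchorable 17-nt core


def simulate_degradome_clones(
    transcript: NucSequence,
    site: tuple[int, int],
    cut_at: int = 10,
    on_target_frac: float = 1.0,
    n: int = 16,
    seed: int = 0,
    frag_len: int = 60,
) -> tuple[list[CloneRead], FixtureTruth]:
    """5'-truncated sense fragments with the programmed cut opposite miRNA
    nucleotide ``cut_at`` with probability ``on_target_frac``, elsewhere in
    the 100-nt window otherwise."""
    if not 0 < on_target_frac <= 1:
        raise ValueError("on_target_frac must be in (0, 1]")
    rng = random.Random(seed)
    tr = dna(transcript).residues
    s_start, s_end = site
    p_cut = s_end - cut_at + 1
    mid = (s_start + s_end) // 2
    lo, hi = max(1, mid - 50), min(len(tr), mid + 50)
    reads = []
    realized = []
    for i in range(n):
        if rng.random() < on_target_frac:
            p = p_cut
        else:
            p = rng.choice([q for q in range(lo, hi + 1) if q != p_cut])
        frag = tr[p - 1 : p - 1 + frag_len]
        reads.append(
            CloneRead(
                id=f"{transcript.id}_deg{i}",
                residues=frag,
                declared_end="five_prime",
                source="simulated-degradome",
            )
        )
        realized.append(p)
    truth = FixtureTruth(
        seed=seed,
        kind="degradome",
        params={
            "site": [s_start, s_end],
            "cut_position_mirna": cut_at,
            "cut_position_transcript": p_cut,
            "on_target_frac": on_target_frac,
            "realized_starts": realized,
        },
    )
    return reads, truth
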