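"""Stem-loop folding and the six-criteria filter for candidate pre-miRNAs.

The folder is a Nussinov-style dynamic program over nested (pseudoknot-free)
structures with a simple per-pair scoring model standing in for a full
nearest-neighbor energy function:

    G:C = -3, A:U = -2, G:U = -1   (pseudo-kcal/mol per pair)

with a minimum hairpin loop of 3 unpaired nucleotides.  The criteria applied
downstream only need pairing topology plus a fold score, so this model keeps
the tool dependency-free and exhaustively testable: for short sequences the
DP provably matches a brute-force enumeration of every nested structure.

Candidate acceptance mirrors the classical homology-search filters for plant
pre-miRNAs:

  1. fold score at most a configured threshold (default -18 pseudo-kcal);
  2. at most 4 substitutions between candidate mature and the known mature;
  3. mature localized on one arm of the hairpin;
  4. the window folds into a stem-loop with the mature substantially paired;
  5. no terminal-loop overlap and no unpaired run longer than ``max_break``
     inside the mature or its star;
  6. at most 6 mismatches in the mature:star duplex (an unpaired mature
     position counts as one mismatch).

Ties between equal-score structures are broken by preferring pairs that
involve the mature span (as a secondary score term), then by a fixed
deterministic traceback order, so folding is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import NucSequence, hamming, rna

try:  # JIT for the O(n^3) fill; pure-numpy fallback keeps numba optional
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

MIN_LOOP = 3  # unpaired nucleotides required inside a hairpin loop
_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
# secondary-score scale: pair weight * _SCALE + (1 if pair touches mature)
_SCALE = 256


class FoldError(ValueError):
    pass


class NoStarError(ValueError):
    """Mature span has no paired partner — no miRNA* can be inferred."""


@dataclass(frozen=True)
class Span:
    """1-based inclusive interval on a precursor."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class HairpinStructure:
    """A folded precursor: pair table (1-based partner, 0 = unpaired) + score."""

    precursor: NucSequence
    pair_table: tuple[int, ...]
    fold_score: float

    def __post_init__(self) -> None:
        n = len(self.precursor)
        pt = self.pair_table
        assert len(pt) == n
        for i, j in enumerate(pt, start=1):
            if j:
                assert pt[j - 1] == i, "pair table not symmetric"

    def dot_bracket(self) -> str:
        return "".join(
            "." if j == 0 else ("(" if j > i else ")")
            for i, j in enumerate(self.pair_table, start=1)
        )

    def hairpin_loops(self) -> list[Span]:
        """Terminal loops: unpaired stretches closed directly by a pair."""
        loops = []
        for i, j in enumerate(self.pair_table, start=1):
            if j > i and all(self.pair_table[k - 1] == 0 for k in range(i + 1, j)):
                loops.append(Span(i + 1, j - 1))
        return loops

    def n_pairs(self) -> int:
        return sum(1 for j in self.pair_table if j) // 2


@dataclass
class CriteriaReport:
    """Per-criterion verdicts plus the measured quantities behind them."""

    fold_score: float
    substitutions: int | None
    arm: str  # '5p' | '3p' | 'loop-overlap' | 'unpaired'
    loop_or_break: bool
    duplex_mismatches: int
    star: Span | None
    criteria: dict[int, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


@dataclass
class HairpinConfig:
    """Thresholds for the six-criteria filter (all surfaced, all logged)."""

    max_fold_score: float = -18.0  # criterion 1 ("high negative MFE")
    max_subs_vs_known: int = 4     # criterion 2
    min_mature_paired_frac: float = 0.5  # criterion 4 stem-loop requirement
    max_break: int = 2             # criterion 5 unpaired-run tolerance
    max_duplex_mismatches: int = 6  # criterion 6
    star_overhang: int = 2         # Dicer-style 2-nt 3' overhang (0-2)
    min_precursor_len: int = 40    # pipeline-level minimum window length


def _encode(residues: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "U": 3}
    return np.array([table.get(c, 4) for c in residues], dtype=np.int64)


_W5 = np.zeros((5, 5), dtype=np.int64)
for (x, y), w in _PAIR_SCORE.items():
    _W5[_encode(x)[0], _encode(y)[0]] = w


if _HAVE_NUMBA:

    @njit(cache=True)
    def _fill(wmat: np.ndarray) -> np.ndarray:  # pragma: no cover - jit
        n = wmat.shape[0]
        m = np.zeros((n + 1, n + 1), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = m[i, j - 1] if j - 1 >= i else 0  # j unpaired
                for k in range(i, j - MIN_LOOP):
                    w = wmat[k, j]
                    if w > 0:
                        left = m[i, k - 1] if k - 1 >= i else 0
                        mid = m[k + 1, j - 1] if k + 1 <= j - 1 else 0
                        cand = left + mid + w
                        if cand > best:
                            best = cand
                m[i, j] = best
        return m

else:  # pragma: no cover - exercised only without numba

    def _fill(wmat: np.ndarray) -> np.ndarray:
        n = wmat.shape[0]
        m = np.zeros((n + 1, n + 1), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            i_idx = np.arange(0, n - span)
            for i in i_idx:
                j = i + span
                best = m[i, j - 1] if j - 1 >= i else 0
                ks = np.arange(i, j - MIN_LOOP)
                ks = ks[wmat[ks, j] > 0]
                if ks.size:
                    left = np.where(ks - 1 >= i, m[i, np.maximum(ks - 1, 0)], 0)
                    mid = m[ks + 1, j - 1]
                    cand = (left + mid + wmat[ks, j]).max()
                    best = max(best, cand)
                m[i, j] = best
        return m


def _traceback(m: np.ndarray, wmat: np.ndarray, n: int) -> list[int]:
    """Deterministic traceback: leave j unpaired when score-equal, else pair
    j with the 5'-most eligible partner."""
    pt = [0] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if m[i, j] == (m[i, j - 1] if j - 1 >= i else 0):
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            w = wmat[k, j]
            if w <= 0:
                continue
            left = m[i, k - 1] if k - 1 >= i else 0
            mid = m[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if left + mid + w == m[i, j]:
                pt[k] = j + 1
                pt[j] = k + 1
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
        else:  # pragma: no cover - recurrence guarantees a branch
            raise AssertionError("traceback failed")
    return pt


def fold_hairpin(
    precursor: NucSequence,
    mature: Span | None = None,
    min_len: int = 1,
) -> HairpinStructure:
    """Maximum-score nested fold of ``precursor`` under the pair model.

    ``mature`` (optional) activates the tie-break preferring structures with
    more pairs touching the mature span; it does not change the optimal pair
    score.  ``min_len`` lets the prediction pipeline enforce its 40-nt
    candidate-window minimum.
    """
    seq = rna(precursor)
    n = len(seq)
    if n < min_len:
        raise FoldError(f"{seq.id!r}: length {n} < minimum {min_len}")
    codes = _encode(seq.residues)
    wmat = _W5[codes[:, None], codes[None, :]] * _SCALE
    if mature is not None:
        touch = np.zeros(n, dtype=bool)
        touch[mature.start - 1 : mature.end] = True
        bonus = (touch[:, None] | touch[None, :]).astype(np.int64)
        wmat = wmat + bonus * (wmat > 0)
    m = _fill(wmat)
    pt = _traceback(m, wmat, n)
    score = 0
    for i0, j1 in enumerate(pt):
        if j1 > i0 + 1:
            score += _PAIR_SCORE[(seq.residues[i0], seq.residues[j1 - 1])]
    return HairpinStructure(seq, tuple(pt), float(-score))


def _max_unpaired_run(pt: tuple[int, ...], span: Span) -> int:
    run = best = 0
    for pos in range(span.start, span.end + 1):
        if 1 <= pos <= len(pt) and pt[pos - 1] == 0:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def duplex_chain(h: HairpinStructure, mature: Span) -> list[tuple[int, int]]:
    """The mature:star duplex as the longest consistent (position, partner)
    chain over the mature span.

    Walking the mature 5'->3', true duplex partners descend steadily; jumps
    up to 3 are bulges within the break tolerance.  Pairs reached only
    through larger jumps (context sequence co-folding around the hairpin,
    or bulges that already count as breaks) split the chain and the longest
    segment wins, which keeps star inference robust on embedded hairpins.
    """
    chains: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for p in range(mature.start, mature.end + 1):
        q = h.pair_table[p - 1]
        if q == 0:
            continue
        if cur and 1 <= cur[-1][1] - q <= 3 and p - cur[-1][0] <= 3:
            cur.append((p, q))
        else:
            if cur:
                chains.append(cur)
            cur = [(p, q)]
    if cur:
        chains.append(cur)
    return max(chains, key=len) if chains else []


def mature_arm(h: HairpinStructure, mature: Span) -> str:
    """'5p' / '3p' when the mature duplex sits on one arm, else degenerate.

    A mature whose duplex chain covers less than half its length (e.g. one
    straddling the terminal loop, pairing half upstream and half downstream)
    is not localized to an arm.
    """
    chain = duplex_chain(h, mature)
    if not chain:
        return "unpaired"
    if len(chain) < 0.5 * len(mature):
        return "loop-overlap"
    partners = [q for _, q in chain]
    if all(q > mature.end for q in partners):
        return "5p"
    if all(q < mature.start for q in partners):
        return "3p"
    return "loop-overlap"


def infer_star(h: HairpinStructure, mature: Span, overhang: int = 2) -> Span:
    """miRNA* span: the positions opposite the mature duplex, shifted by the
    Dicer-style 2-nt 3' overhang convention (configurable 0-2)."""
    arm = mature_arm(h, mature)
    if arm in ("unpaired", "loop-overlap"):
        raise NoStarError(f"mature {mature.start}..{mature.end} is {arm}")
    partners = [q for _, q in duplex_chain(h, mature)]
    lo, hi = min(partners), max(partners)
    n = len(h.precursor)
    shift = overhang if arm == "5p" else -overhang
    start = min(max(1, lo + shift), n)
    end = min(max(1, hi + shift), n)
    star = Span(start, end)
    if not (star.end < mature.start or star.start > mature.end):
        raise NoStarError("inferred star overlaps the mature span")
    return star


def duplex_mismatch_count(h: HairpinStructure, mature: Span) -> int:
    """Unpaired mature positions = mismatches in the mature:star duplex."""
    return sum(
        1 for p in range(mature.start, mature.end + 1) if h.pair_table[p - 1] == 0
    )


def evaluate_criteria(
    h: HairpinStructure,
    mature: Span,
    known: NucSequence | None = None,
    config: HairpinConfig | None = None,
) -> CriteriaReport:
    """Apply the six acceptance criteria; always returns a full report."""
    cfg = config or HairpinConfig()
    if mature.end > len(h.precursor):
        raise ValueError("mature span outside precursor")

    arm = mature_arm(h, mature)
    dmm = duplex_mismatch_count(h, mature)

    subs: int | None = None
    if known is not None:
        mat_seq = NucSequence(
            "mature", h.precursor.residues[mature.start - 1 : mature.end], "RNA"
        )
        subs = hamming(mat_seq, known)

    star: Span | None = None
    try:
        star = infer_star(h, mature, cfg.star_overhang)
    except NoStarError:
        star = None

    loops = h.hairpin_loops()
    in_loop = lambda s: any(
        not (s.end < lp.start or s.start > lp.end) for lp in loops
    )
    break_flag = (
        arm in ("unpaired", "loop-overlap")
        or in_loop(mature)
        or star is None
        or in_loop(star)
        or _max_unpaired_run(h.pair_table, mature) > cfg.max_break
        or _max_unpaired_run(h.pair_table, star) > cfg.max_break
    )

    paired_in_mature = len(mature) - dmm
    criteria = {
        1: h.fold_score <= cfg.max_fold_score,
        2: subs is None or subs <= cfg.max_subs_vs_known,
        3: arm in ("5p", "3p"),
        4: h.n_pairs() > 0
        and paired_in_mature >= cfg.min_mature_paired_frac * len(mature),
        5: not break_flag,
        6: dmm <= cfg.max_duplex_mismatches,
    }
    return CriteriaReport(
        fold_score=h.fold_score,
        substitutions=subs,
        arm=arm,
        loop_or_break=break_flag,
        duplex_mismatches=dmm,
        star=star,
        criteria=criteria,
    )


def criteria_tsv_row(candidate_id: str, r: CriteriaReport) -> str:
    flags = "\t".join(str(int(r.criteria[k])) for k in range(1, 7))
    return (
        f"{candidate_id}\t{r.fold_score:.1f}\t"
        f"{'' if r.substitutions is None else r.substitutions}\t{r.arm}\t"
        f"{int(r.loop_or_break)}\t{r.duplex_mismatches}\t{flags}\t"
        f"{int(r.passed)}"
    )


CRITERIA_TSV_HEADER = (
    "candidate\tfold_score\tsubstitutions\tarm\tloop_or_break\t"
    "duplex_mismatches\tc1\tc2\tc3\tc4\tc5\tc6\tpass"
)
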