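"""Antiparallel duplex modeling.

Two views of a miRNA:target interaction are exposed:

* ``pair_gapless`` -- position-by-position antiparallel pairing of two
  equal-length strands, with bond-class counts (A:U, G:C, G:U wobble) and
  percent complementarity of the query. This is the "how many of the miRNA's
  nucleotides pair" view used to rank candidate target mRNAs.
* ``find_best_site`` -- a dynamic program that locates the best-scoring
  intermolecular duplex of a short strand within a long one (the anti-miR /
  target-prediction question: where does a ~22-mer bind a ~700-nt 3'-UTR?).

The site finder uses simple additive pair rewards with affine bulge
penalties. It deliberately does not model nearest-neighbor thermodynamics:
the contract is "best-fitting site of a short strand in a long one", not a
free-energy estimate, and its scoring parameters are all configurable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Union

from .seqcore import (
    Alphabet,
    ContractError,
    NucleicSeq,
    PNAChain,
    PairClass,
    base_pair_class,
    to_rna,
)

__all__ = [
    "DuplexScoring",
    "DuplexAlignment",
    "BondCounts",
    "SiteHit",
    "pair_gapless",
    "percent_complementarity",
    "find_best_site",
    "score_duplex",
    "render_duplex",
]

SeqLike = Union[NucleicSeq, PNAChain, str]


def _as_rna_string(seq: SeqLike, name: str = "seq") -> str:
    """Accept NucleicSeq / PNAChain / plain string; return RNA-lettered residues."""
    if isinstance(seq, PNAChain):
        return seq.as_rna().residues
    if isinstance(seq, str):
        seq = NucleicSeq(name, seq, Alphabet.DNA if "T" in seq.upper() else Alphabet.RNA)
    return to_rna(seq).residues


@dataclass(frozen=True)
class DuplexScoring:
    """Additive scoring for intermolecular duplexes.

    Rewards reflect relative pair stability (G:C > A:U > G:U); bulges on
    either strand pay an affine penalty. ``allow_gaps=False`` restricts the
    search to gapless windows.
    """

    reward_gc: float = 3.0
    reward_au: float = 2.0
    reward_gu: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -4.0
    gap_extend: float = -2.0
    allow_wobble: bool = True
    allow_gaps: bool = True

    def pair_reward(self, cls: PairClass) -> float:
        return {
            PairClass.WC_GC: self.reward_gc,
            PairClass.WC_AU: self.reward_au,
            PairClass.GU: self.reward_gu,
            PairClass.NONE: self.mismatch,
        }[cls]


#: G:U wobble is off for PNA:RNA duplexes -- PNAs are screened strict Watson-Crick.
PNA_SCORING = DuplexScoring(allow_wobble=False, allow_gaps=False)


@dataclass(frozen=True)
class DuplexAlignment:
    """An antiparallel pairing map between a query and a target window.

    ``pairs`` holds (query_pos, target_pos, pair_class) triples, 0-based,
    paired positions only; as query_pos increases target_pos strictly
    decreases (antiparallel geometry). ``target_window`` is 0-based half-open
    on the target.
    """

    query: str
    target: str
    pairs: tuple[tuple[int, int, PairClass], ...]
    target_window: tuple[int, int]
    query_name: str = "query"
    target_name: str = "target"

    def __post_init__(self) -> None:
        qseen: set[int] = set()
        tseen: set[int] = set()
        prev_t = None
        for q, t, cls in self.pairs:
            if cls is PairClass.NONE:
                raise ContractError("pairs must not contain NONE entries")
            if q in qseen or t in tseen:
                raise ContractError("a position appears in more than one pair")
            qseen.add(q)
            tseen.add(t)
            if prev_t is not None and t >= prev_t:
                raise ContractError("pairing map is not antiparallel-monotone")
            prev_t = t


@dataclass(frozen=True)
class BondCounts:
    """Bond-class tally for a duplex: n_au A:U pairs, n_gc G:C pairs,
    n_gu G:U wobbles, out of query_len query positions."""

    n_au: int
    n_gc: int
    n_gu: int
    query_len: int

    @property
    def n_paired(self) -> int:
        return self.n_au + self.n_gc + self.n_gu


@dataclass(frozen=True)
class SiteHit:
    """A binding site on the long strand: 1-based inclusive interval,
    duplex score, and the alignment itself."""

    target_interval: tuple[int, int]
    score: float
    duplex: DuplexAlignment


def pair_gapless(
    query: SeqLike, target_site: SeqLike, allow_wobble: bool = False
) -> tuple[DuplexAlignment, BondCounts]:
    """Pair two equal-length strands antiparallel, position by position.

    Query position i is tested against site position L-1-i. Wobble defaults
    off (the PNA:RNA convention); pass ``allow_wobble=True`` for miRNA:mRNA
    duplexes.
    """
    q = _as_rna_string(query, "query")
    t = _as_rna_string(target_site, "site")
    if len(q) != len(t):
        raise ContractError(f"gapless pairing needs equal lengths, got {len(q)} vs {len(t)}")
    n = len(q)
    pairs = []
    counts = {PairClass.WC_AU: 0, PairClass.WC_GC: 0, PairClass.GU: 0}
    for i in range(n):
        cls = base_pair_class(q[i], t[n - 1 - i], allow_wobble=allow_wobble)
        if cls is not PairClass.NONE:
            pairs.append((i, n - 1 - i, cls))
            counts[cls] += 1
    duplex = DuplexAlignment(q, t, tuple(pairs), (0, n))
    bonds = BondCounts(
        n_au=counts[PairClass.WC_AU],
        n_gc=counts[PairClass.WC_GC],
        n_gu=counts[PairClass.GU],
        query_len=n,
    )
    return duplex, bonds


def percent_complementarity(counts: BondCounts) -> float:
    """Fraction of query positions paired, in [0, 1].

    Note the exact fraction is reported (e.g. 20/23 = 0.8696), with no
    presentation rounding.
    """
    if counts.query_len == 0:
        raise ContractError("query_len must be positive")
    return counts.n_paired / counts.query_len


def score_duplex(duplex: DuplexAlignment, scoring: DuplexScoring) -> float:
    """Re-score an alignment from its pairing map.

    Sum of pair rewards, plus mismatch scores and one affine bulge penalty
    per inter-pair region (the cheapest arrangement of the unpaired bases
    between consecutive pairs, which is what the site finder's traceback
    produces).
    """
    total = 0.0
    prev = None
    for q, t, cls in duplex.pairs:
        total += scoring.pair_reward(cls)
        if prev is not None:
            dq = q - prev[0] - 1
            dt = prev[1] - t - 1
            total += scoring.mismatch * min(dq, dt)
            gap = abs(dq - dt)
            if gap:
                total += scoring.gap_open + scoring.gap_extend * (gap - 1)
        prev = (q, t)
    return total


def _gapless_window_score(q: str, t: str, start: int, scoring: DuplexScoring) -> float:
    n = len(q)
    total = 0.0
    for i in range(n):
        cls = base_pair_class(q[i], t[start + n - 1 - i], allow_wobble=scoring.allow_wobble)
        total += scoring.pair_reward(cls)
    return total


def _best_gapless(q, t, lo, hi, scoring):
    """Best full-query window inside t[lo:hi]; ties -> smallest start."""
    n = len(q)
    if hi - lo < n:
        return None
    best = None
    for start in range(lo, hi - n + 1):
        s = _gapless_window_score(q, t, start, scoring)
        if best is None or s > best[0]:
            best = (s, start)
    score, start = best
    dup, _ = pair_gapless(q, t[start : start + n], allow_wobble=scoring.allow_wobble)
    pairs = tuple((qp, start + tp, cls) for qp, tp, cls in dup.pairs)
    return score, pairs, (start, start + n)

_NEG = float("-inf")


def _best_gapped(q, t, lo, hi, scoring):
    """Affine-gap fit alignment of the full query inside t[lo:hi].

    The reversed segment makes the antiparallel pairing co-linear; three
    Gotoh matrices (pair/mismatch diagonal, target bulge, query bulge) with
    free leading/trailing target. Ties break toward the smallest target
    start coordinate.
    """
    seg = t[lo:hi]
    m = len(seg)
    n = len(q)
    if m == 0:
        return None
    r = seg[::-1]
    cls_of = [
        [base_pair_class(q[i], r[j], allow_wobble=scoring.allow_wobble) for j in range(m)]
        for i in range(n)
    ]
    go, ge = scoring.gap_open, scoring.gap_extend

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # target base bulged
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # query base bulged
    ptrM = [[None] * (m + 1) for _ in range(n + 1)]
    ptrX = [[None] * (m + 1) for _ in range(n + 1)]
    ptrY = [[None] * (m + 1) for _ in range(n + 1)]

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal: q[i-1] faces r[j-1] (pair or mismatch)
            sc = scoring.pair_reward(cls_of[i - 1][j - 1])
            if i == 1:
                M[i][j] = sc  # query starts here; leading target is free
                ptrM[i][j] = "start"
            else:
                best, src = M[i - 1][j - 1], "M"
                if X[i - 1][j - 1] > best:
                    best, src = X[i - 1][j - 1], "X"
                if Y[i - 1][j - 1] > best:
                    best, src = Y[i - 1][j - 1], "Y"
                if best > _NEG:
                    M[i][j] = best + sc
                    ptrM[i][j] = src
            # target bulge: consume r[j-1] unpaired
            a = M[i][j - 1] + go if M[i][j - 1] > _NEG else _NEG
            b = X[i][j - 1] + ge if X[i][j - 1] > _NEG else _NEG
            if a >= b and a > _NEG:
                X[i][j], ptrX[i][j] = a, "M"
            elif b > _NEG:
                X[i][j], ptrX[i][j] = b, "X"
            # query bulge: consume q[i-1] unpaired
            if i > 1:
                a = M[i - 1][j] + go if M[i - 1][j] > _NEG else _NEG
                b = Y[i - 1][j] + ge if Y[i - 1][j] > _NEG else _NEG
                if a >= b and a > _NEG:
                    Y[i][j], ptrY[i][j] = a, "M"
                elif b > _NEG:
                    Y[i][j], ptrY[i][j] = b, "Y"

    # endpoint: full query consumed, trailing target free; ties -> largest j
    # in reversed coords == smallest target start
    best_score, end_j, end_state = _NEG, None, None
    for j in range(1, m + 1):
        for state, row in (("M", M[n]), ("Y", Y[n])):
            if row[j] > best_score or (row[j] == best_score and end_j is not None and j > end_j):
                best_score, end_j, end_state = row[j], j, state
    if end_j is None:
        return None

    # traceback
    pairs = []
    cols = []  # consumed reversed-segment columns
    i, j, state = n, end_j, end_state
    while i > 0:
        if state == "M":
            cls = cls_of[i - 1][j - 1]
            cols.append(j - 1)
            if cls is not PairClass.NONE:
                pairs.append((i - 1, lo + m - 1 - (j - 1), cls))
            src = ptrM[i][j]
            i, j = i - 1, j - 1
            if src == "start":
                break
            state = src
        elif state == "X":
            cols.append(j - 1)
            src = ptrX[i][j]
            j -= 1
            state = src
        else:  # Y
            src = ptrY[i][j]
            i -= 1
            state = src
    pairs.reverse()
    if not cols:
        return None
    t_positions = [lo + m - 1 - c for c in cols]
    window = (min(t_positions), max(t_positions) + 1)
    return best_score, tuple(pairs), window


def find_best_site(
    short: SeqLike,
    long: SeqLike,
    scoring: DuplexScoring | None = None,
    k: int = 1,
    query_name: str = "query",
    target_name: str = "target",
) -> list[SiteHit]:
    """Top-k non-overlapping binding sites of ``short`` within ``long``.

    Greedy by score: the best site is accepted, then the search recurses on
    the target stretches left of and right of it, so no two reported
    intervals overlap. Deterministic; equal scores break toward the smallest
    target start. Intervals in the returned hits are 1-based inclusive.
    """
    scoring = scoring or DuplexScoring()
    q = _as_rna_string(short, "short")
    t = _as_rna_string(long, "long")
    if not q or not t:
        raise ContractError("empty sequence")
    if len(q) > len(t):
        raise ContractError("short strand is longer than the long one")

    solver = _best_gapped if scoring.allow_gaps else _best_gapless

    def make_hit(res):
        score, pairs, window = res
        dup = DuplexAlignment(q, t, pairs, window, query_name, target_name)
        return SiteHit((window[0] + 1, window[1]), score, dup)

    hits: list[SiteHit] = []
    heap = []
    counter = 0  # tie-breaker for heap stability
    first = solver(q, t, 0, len(t), scoring)
    if first is not None:
        heapq.heappush(heap, (-first[0], first[2][0], counter, first, 0, len(t)))
    while heap and len(hits) < k:
        _, _, _, res, lo, hi = heapq.heappop(heap)
        hit = make_hit(res)
        hits.append(hit)
        w_lo, w_hi = res[2]
        for sub_lo, sub_hi in ((lo, w_lo), (w_hi, hi)):
            if sub_hi - sub_lo >= (len(q) if not scoring.allow_gaps else 1):
                sub = solver(q, t, sub_lo, sub_hi, scoring)
                if sub is not None:
                    counter += 1
                    heapq.heappush(heap, (-sub[0], sub[2][0], counter, sub, sub_lo, sub_hi))
    return hits


_MARK = {PairClass.WC_AU: "|", PairClass.WC_GC: "|", PairClass.GU: ":"}


def render_duplex(duplex: DuplexAlignment) -> str:
    """Three-line text diagram: query 5'->3', pairing marks, target 3'->5'.

    '|' marks Watson-Crick pairs, ':' marks G:U wobbles; bulged positions
    show '-' on the opposite strand.
    """
    q = duplex.query
    w_lo, w_hi = duplex.target_window
    t_rev_positions = list(range(w_hi - 1, w_lo - 1, -1))  # target read 3'->5'
    q_by_t = {t: (qp, cls) for qp, t, cls in duplex.pairs}
    t_by_q = {qp: t for qp, t, _ in duplex.pairs}

    top, mid, bot = [], [], []
    qi, ti_idx = 0, 0
    while qi < len(q) or ti_idx < len(t_rev_positions):
        tpos = t_rev_positions[ti_idx] if ti_idx < len(t_rev_positions) else None
        paired_here = tpos is not None and tpos in q_by_t and q_by_t[tpos][0] == qi
        if paired_here:
            top.append(q[qi])
            mid.append(_MARK[q_by_t[tpos][1]])
            bot.append(duplex.target[tpos])
            qi += 1
            ti_idx += 1
        elif qi < len(q) and qi in t_by_q:
            # query waits for its partner: target bulge
            top.append("-")
            mid.append(" ")
            bot.append(duplex.target[tpos] if tpos is not None else "-")
            ti_idx += 1
        elif tpos is not None and tpos in q_by_t:
            # target waits for its partner: query bulge
            top.append(q[qi] if qi < len(q) else "-")
            mid.append(" ")
            bot.append("-")
            qi += 1
        else:
            # mismatch column (or unpaired overhang)
            top.append(q[qi] if qi < len(q) else "-")
            mid.append(" ")
            bot.append(duplex.target[tpos] if tpos is not None else "-")
            if qi < len(q):
                qi += 1
            if tpos is not None:
                ti_idx += 1
    return "\n".join(
        [
            f"{duplex.query_name} 5'-{''.join(top)}-3'",
            " " * (len(duplex.query_name) + 4) + "".join(mid),
            f"{duplex.target_name} 3'-{''.join(bot)}-5'",
        ]
    )
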