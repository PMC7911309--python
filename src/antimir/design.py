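"""Anti-miR PNA design engine.

A candidate anti-miR is the T-lettered reverse complement of a window of the
mature miRNA. Candidates are screened on four criteria:

(a) fixed length (default 18 bases, convenient for large-scale synthesis);
(b) lack of self-complementarity, in both antiparallel and parallel
    orientation (PNA:PNA duplexes form in either geometry);
(c) no long exact complementary stretch in non-target transcripts
    (an off-target screen; candidates can also be exported as FASTA for an
    external BLAST search);
(d) coverage of the miRNA seed region (nucleotides 2-8), the primary
    determinant of target recognition.

A matched negative control is produced by permuting nucleobases among a fixed
number of positions, preserving base composition (and therefore conjugate
mass) while suppressing hybridization to the miRNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqcore import ContractError, NucleicSeq, PNAChain, reverse_complement, to_dna
from .duplex import PNA_SCORING, find_best_site, pair_gapless

__all__ = [
    "DesignCriteria",
    "DesignReport",
    "OfftargetHit",
    "ScrambleResult",
    "InfeasibleDesignError",
    "enumerate_candidates",
    "self_complementarity",
    "offtarget_scan",
    "make_scrambled_control",
    "validate_design",
]


class InfeasibleDesignError(RuntimeError):
    """No sequence satisfying the requested constraints exists / was found."""


_DNA_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class DesignCriteria:
    """Screening thresholds.

    seed_interval is 1-based inclusive on the miRNA. A candidate passes the
    self-complementarity screen when its longest self-pairing run (either
    orientation) is at most max_self_comp_run, and the off-target screen when
    no transcript carries a complementary stretch longer than
    max_offtarget_run.
    """

    pna_length: int = 18
    seed_interval: tuple[int, int] = (2, 8)
    max_self_comp_run: int = 3
    max_offtarget_run: int = 12
    scramble_changes: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.seed_interval
        if not (1 <= lo <= hi):
            raise ContractError("seed_interval must be 1-based and non-empty")
        if self.pna_length < hi - lo + 1:
            raise ContractError("pna_length shorter than the seed span")
        if min(self.max_self_comp_run, self.max_offtarget_run) < 0:
            raise ContractError("thresholds must be non-negative")


@dataclass(frozen=True)
class OfftargetHit:
    """Longest exact complementary stretch between a PNA and one transcript.

    ``interval`` is 1-based inclusive on the transcript; orientation is
    'antiparallel' (canonical binding) or 'parallel'. run == 0 means no
    complementary base at all (interval is None).
    """

    transcript: str
    run: int
    interval: tuple[int, int] | None
    orientation: str | None


@dataclass(frozen=True)
class DesignReport:
    """Per-candidate outcome of all screening criteria."""

    candidate: PNAChain
    mirna_window: tuple[int, int]  # 1-based inclusive on the miRNA
    seed_covered: bool
    self_comp_antiparallel: int
    self_comp_parallel: int
    offtarget_runs: tuple[OfftargetHit, ...]
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def composition(self) -> Counter:
        return Counter(self.candidate.bases)

    @property
    def passes_all(self) -> bool:
        return all(self.passes.values())


def _covers_seed(window: tuple[int, int], seed: tuple[int, int]) -> bool:
    return window[0] <= seed[0] and window[1] >= seed[1]


def enumerate_candidates(
    mirna: NucleicSeq, criteria: DesignCriteria | None = None,
    transcripts: list[NucleicSeq] | None = None,
) -> list[DesignReport]:
    """All sliding-window anti-miR candidates against a mature miRNA.

    A miRNA of length L yields L - pna_length + 1 candidates, each the
    T-lettered reverse complement of its window, fully validated against the
    criteria (off-target screening only if transcripts are supplied).
    """
    criteria = criteria or DesignCriteria()
    L = criteria.pna_length
    if len(mirna) < L:
        raise ContractError(f"miRNA ({len(mirna)} nt) shorter than pna_length ({L})")
    reports = []
    for start in range(len(mirna) - L + 1):
        window_seq = NucleicSeq(
            f"{mirna.name}[{start + 1}-{start + L}]",
            mirna.residues[start : start + L],
            mirna.alphabet,
        )
        candidate = PNAChain(to_dna(reverse_complement(window_seq)).residues)
        reports.append(
            validate_design(
                candidate,
                mirna,
                transcripts or [],
                criteria,
                mirna_window=(start + 1, start + L),
            )
        )
    return reports


def _longest_true_run(flags: list[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def self_complementarity(pna: PNAChain) -> tuple[int, int]:
    """Longest self-pairing runs of a chain against a second copy of itself.

    Antiparallel: the copy is reversed (position i vs L-1-(i+offset));
    parallel: the copy is unreversed (position i vs i+offset). Both scan all
    relative offsets exhaustively; Watson-Crick pairs only (no wobble --
    PNA strands are T-lettered).

    Returns (antiparallel_run, parallel_run).
    """
    s = pna.bases
    L = len(s)
    runs = []
    for other in (s[::-1], s):
        best = 0
        for offset in range(-(L - 1), L):
            flags = [
                _DNA_PAIR[s[i]] == other[i + offset]
                for i in range(max(0, -offset), min(L, L - offset))
            ]
            best = max(best, _longest_true_run(flags))
        runs.append(best)
    return runs[0], runs[1]


def _longest_complementary_run(pna: str, strand: str) -> tuple[int, int | None]:
    """Longest common stretch where pna[i..] is base-by-base complementary to
    strand[j..]; O(n*m) suffix DP. Returns (run, end index in strand)."""
    n, m = len(pna), len(strand)
    best, best_end = 0, None
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        comp = _DNA_PAIR[pna[i - 1]]
        for j in range(1, m + 1):
            if strand[j - 1] == comp:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best, best_end = cur[j], j - 1
        prev = cur
    return best, best_end


def offtarget_scan(pna: PNAChain, transcripts: list[NucleicSeq]) -> list[OfftargetHit]:
    """Per-transcript longest exact complementary stretch.

    Both binding geometries are scanned: antiparallel (PNA vs the reversed
    transcript, the canonical duplex) and parallel (PNA vs the transcript as
    written). The reported hit is the longer of the two; its interval is
    1-based inclusive in transcript coordinates. Empty transcript list gives
    an empty report.
    """
    hits = []
    for tx in transcripts:
        t = to_dna(tx).residues
        best_run, best_iv, best_ori = 0, None, None
        for ori, strand in (("antiparallel", t[::-1]), ("parallel", t)):
            run, end = _longest_complementary_run(pna.bases, strand)
            if run > best_run:
                if ori == "parallel":
                    iv = (end - run + 2, end + 1)
                else:  # map reversed coordinates back
                    e = len(t) - 1 - (end - run + 1)
                    iv = (e - run + 2, e + 1)
                best_run, best_iv, best_ori = run, iv, ori
        hits.append(OfftargetHit(tx.name, best_run, best_iv, best_ori))
    return hits


@dataclass(frozen=True)
class ScrambleResult:
    """A composition-preserving scrambled control plus its validation record."""

    control: PNAChain
    changed_positions: tuple[int, ...]  # 1-based
    hamming: int
    residual_run: int | None  # longest complementary run vs verify_vs, if given
    attempts: int


def make_scrambled_control(
    pna: PNAChain,
    n_changes: int = 4,
    seed: int = 0,
    verify_vs: NucleicSeq | None = None,
    max_residual_run: int = 8,
    max_attempts: int = 10_000,
) -> ScrambleResult:
    """Scramble the position of ``n_changes`` nucleobases.

    The control keeps the exact base multiset of the input (changes are
    realized by permuting existing bases, never substituting) and differs
    from it at exactly ``n_changes`` positions. When ``verify_vs`` is given
    (normally the target miRNA), candidates whose longest residual
    complementary run exceeds ``max_residual_run`` are rejected, so the
    control no longer hybridizes.

    Seeded rejection sampling; deterministic for a given seed. Raises
    InfeasibleDesignError when no valid control exists or none is found
    within ``max_attempts``.
    """
    if n_changes < 2:
        raise ContractError("n_changes must be at least 2 (bases are permuted, not substituted)")
    s = list(pna.bases)
    if n_changes > len(s):
        raise ContractError("n_changes exceeds chain length")
    if len(set(s)) < 2:
        raise InfeasibleDesignError(
            "homopolymer chain: no composition-preserving permutation changes any position"
        )
    rng = np.random.default_rng(seed)
    verify_dna = to_dna(verify_vs).residues if verify_vs is not None else None
    for attempt in range(1, max_attempts + 1):
        pos = rng.choice(len(s), size=n_changes, replace=False)
        perm = rng.permutation(n_changes)
        cand = s.copy()
        for k, p in enumerate(pos):
            cand[p] = s[pos[perm[k]]]
        if any(cand[p] == s[p] for p in pos):
            continue  # a permuted base landed on an identical letter
        control = "".join(cand)
        residual = None
        if verify_dna is not None:
            residual, _ = _longest_complementary_run(control, verify_dna[::-1])
            if residual > max_residual_run:
                continue
        changed = tuple(sorted(int(p) + 1 for p in pos))
        return ScrambleResult(PNAChain(control), changed, n_changes, residual, attempt)
    raise InfeasibleDesignError(
        f"no valid scramble found in {max_attempts} attempts "
        f"(n_changes={n_changes}, max_residual_run={max_residual_run})"
    )


def validate_design(
    pna: PNAChain,
    mirna: NucleicSeq,
    transcripts: list[NucleicSeq],
    criteria: DesignCriteria | None = None,
    mirna_window: tuple[int, int] | None = None,
) -> DesignReport:
    """Full criteria screen of one candidate against its miRNA.

    If ``mirna_window`` is not given, it is located as the miRNA window whose
    reverse complement the candidate is (best gapless full-pairing placement).
    """
    criteria = criteria or DesignCriteria()
    if mirna_window is None:
        hits = find_best_site(pna, mirna, scoring=PNA_SCORING)
        mirna_window = hits[0].target_interval if hits else (1, len(pna))
    anti, para = self_complementarity(pna)
    off = offtarget_scan(pna, transcripts)
    seed_ok = _covers_seed(mirna_window, criteria.seed_interval)
    passes = {
        "length": len(pna) == criteria.pna_length,
        "self_complementarity": max(anti, para) <= criteria.max_self_comp_run,
        "offtarget": all(h.run <= criteria.max_offtarget_run for h in off),
        "seed": seed_ok,
    }
    return DesignReport(
        candidate=pna,
        mirna_window=mirna_window,
        seed_covered=seed_ok,
        self_comp_antiparallel=anti,
        self_comp_parallel=para,
        offtarget_runs=tuple(off),
        passes=passes,
    )
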