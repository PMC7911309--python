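"""Candidate enumeration, self-complementarity, off-target scan, scrambling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antimir import (
    Alphabet,
    ContractError,
    DesignCriteria,
    InfeasibleDesignError,
    NucleicSeq,
    PNAChain,
    enumerate_candidates,
    make_scrambled_control,
    offtarget_scan,
    reverse_complement,
    self_complementarity,
    to_dna,
    to_rna,
    validate_design,
)

_DNA_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}

pna_text = st.text(alphabet="ACGT", min_size=2, max_size=24)


def brute_self_comp(s: str) -> tuple[int, int]:
    """Oracle: longest pairing run at every offset against the reversed
    (antiparallel) and unreversed (parallel) copy."""
    L = len(s)
    out = []
    for other in (s[::-1], s):
        best = 0
        for off in range(-(L - 1), L):
            run = 0
            for i in range(L):
                j = i + off
                if 0 <= j < L and _DNA_PAIR[s[i]] == other[j]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
        out.append(best)
    return out[0], out[1]


def brute_offtarget_run(pna: str, transcript: str) -> int:
    """Oracle: longest substring of the PNA whose base-wise complement occurs
    in the transcript or its reverse."""
    best = 0
    for a in range(len(pna)):
        for b in range(a + 1, len(pna) + 1):
            comp = "".join(_DNA_PAIR[c] for c in pna[a:b])
            if comp in transcript or comp in transcript[::-1]:
                best = max(best, b - a)
    return best


class TestEnumerateCandidates:
    def test_sliding_window_count(self, mir335):
        assert len(enumerate_candidates(mir335)) == len(mir335) - 18 + 1 == 6

    def test_first_window_yields_published_antimir(self, mir335, pna_a335):
        reports = enumerate_candidates(mir335)
        first = reports[0]
        assert first.candidate.bases == pna_a335.bases
        assert first.mirna_window == (1, 18)
        assert first.seed_covered  # seed nt 2-8 inside window 1-18

    def test_late_window_misses_seed(self, mir335):
        last = enumerate_candidates(mir335)[-1]
        assert last.mirna_window == (6, 23)
        assert not last.seed_covered

    def test_exact_length_mirna_gives_single_candidate(self):
        mir = NucleicSeq("m", "ACGUACGUACGUACGUAC")
        reports = enumerate_candidates(mir)
        assert len(reports) == 1 and reports[0].mirna_window == (1, 18)

    def test_short_mirna_rejected(self):
        with pytest.raises(ContractError):
            enumerate_candidates(NucleicSeq("m", "ACGU"))

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACGU", min_size=18, max_size=26))
    def test_every_candidate_reverse_complements_to_its_window(self, residues):
        mir = NucleicSeq("m", residues)
        for rep in enumerate_candidates(mir):
            lo, hi = rep.mirna_window
            window = mir.residues[lo - 1 : hi]
            back = to_rna(reverse_complement(NucleicSeq("c", rep.candidate.bases, "DNA")))
            assert back.residues == window


class TestSelfComplementarity:
    @pytest.mark.parametrize(
        "chain,anti,para",
        [
            ("AAAATTTT", 8, 4),  # self-reverse-complement palindrome
            ("AAAAAAAA", 0, 0),  # A cannot pair with A
        ],
    )
    def test_known_runs(self, chain, anti, para):
        assert self_complementarity(PNAChain(chain)) == (anti, para)

    def test_parallel_run_at_shifted_offset(self):
        anti, para = self_complementarity(PNAChain("ATATAT"))
        assert para >= 5

    @settings(derandomize=True, max_examples=150)
    @given(pna_text)
    def test_matches_brute_force(self, chain):
        assert self_complementarity(PNAChain(chain)) == brute_self_comp(chain)

    @settings(derandomize=True, max_examples=100)
    @given(pna_text)
    def test_antiparallel_run_invariant_under_reverse_complement(self, chain):
        rc = to_dna(reverse_complement(NucleicSeq("s", chain, Alphabet.DNA))).residues
        assert self_complementarity(PNAChain(chain))[0] == self_complementarity(PNAChain(rc))[0]


class TestOfftargetScan:
    def test_embedded_full_complement_found(self, pna_a335):
        rc = to_rna(reverse_complement(NucleicSeq("c", pna_a335.bases, "DNA"))).residues
        tx = NucleicSeq("tx", "ACGU" * 20 + rc + "UGCA" * 20)
        (hit,) = offtarget_scan(pna_a335, [tx])
        assert hit.run == 18
        assert hit.interval == (81, 98)
        assert hit.orientation == "antiparallel"

    def test_no_complement_possible(self):
        (hit,) = offtarget_scan(PNAChain("CCCC"), [NucleicSeq("tx", "AAAAAAAA")])
        assert hit.run == 0 and hit.interval is None

    def test_empty_transcript_set(self, pna_a335):
        assert offtarget_scan(pna_a335, []) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        pna = PNAChain("".join(rng.choice(list("ACGT"), 18)))
        for _ in range(25):
            tx = NucleicSeq("tx", "".join(rng.choice(list("ACGU"), 120)))
            (hit,) = offtarget_scan(pna, [tx])
            assert hit.run == brute_offtarget_run(pna.bases, to_dna(tx).residues)


class TestScrambledControl:
    def test_published_control_satisfies_the_contract(self, pna_a335, pna_a335_mut):
        """The study's own control: identical composition, exactly four
        changed positions (4, 8, 13, 17)."""
        assert Counter(pna_a335.bases) == Counter(pna_a335_mut.bases) == Counter(
            {"T": 10, "C": 3, "G": 3, "A": 2}
        )
        diffs = [i + 1 for i, (a, b) in enumerate(zip(pna_a335.bases, pna_a335_mut.bases)) if a != b]
        assert diffs == [4, 8, 13, 17]

    def test_generated_control_properties(self, pna_a335, mir335_site):
        res = make_scrambled_control(pna_a335, n_changes=4, seed=9, verify_vs=mir335_site)
        assert Counter(res.control.bases) == Counter(pna_a335.bases)
        hamming = sum(a != b for a, b in zip(res.control.bases, pna_a335.bases))
        assert hamming == res.hamming == 4
        assert res.residual_run is not None and res.residual_run <= 8

    def test_deterministic_per_seed(self, pna_a335):
        a = make_scrambled_control(pna_a335, seed=5)
        b = make_scrambled_control(pna_a335, seed=5)
        c = make_scrambled_control(pna_a335, seed=6)
        assert a.control == b.control and a.changed_positions == b.changed_positions
        assert c.control != a.control or c.changed_positions != a.changed_positions

    def test_homopolymer_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            make_scrambled_control(PNAChain("AAAAAAAA"), n_changes=4, seed=0)

    def test_too_few_changes_rejected(self, pna_a335):
        with pytest.raises(ContractError):
            make_scrambled_control(pna_a335, n_changes=1, seed=0)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_composition_always_preserved(self, seed):
        parent = PNAChain("TTTCGTTATTGCTCTTGA")
        res = make_scrambled_control(parent, n_changes=4, seed=seed)
        assert Counter(res.control.bases) == Counter(parent.bases)


class TestValidateDesign:
    def test_published_antimir_passes_length_and_seed(self, pna_a335, mir335):
        rep = validate_design(pna_a335, mir335, [], mirna_window=(1, 18))
        assert rep.passes["length"] and rep.passes["seed"]

    def test_self_complementary_hairpin_fails(self):
        mir = NucleicSeq("m", to_rna(reverse_complement(NucleicSeq("x", "AAAAAAAAATTTTTTTTT", "DNA"))).residues)
        rep = validate_design(PNAChain("AAAAAAAAATTTTTTTTT"), mir, [], mirna_window=(1, 18))
        assert not rep.passes["self_complementarity"]
        assert rep.self_comp_antiparallel == 18

    def test_offtarget_threshold_enforced(self, pna_a335, mir335):
        rc = to_rna(reverse_complement(NucleicSeq("c", pna_a335.bases, "DNA"))).residues
        decoy = NucleicSeq("decoy", "ACGU" * 10 + rc + "ACGU" * 10)
        rep = validate_design(pna_a335, mir335, [decoy], mirna_window=(1, 18))
        assert not rep.passes["offtarget"]

    def test_window_located_when_not_given(self, pna_a335, mir335):
        rep = validate_design(pna_a335, mir335, [])
        assert rep.mirna_window == (1, 18)
        assert rep.seed_covered
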