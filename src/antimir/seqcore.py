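"""Sequence and alphabet primitives shared by every other module.

A peptide nucleic acid (PNA) is written N-terminus to C-terminus with DNA
letters (T); a mature miRNA is written 5'->3' with RNA letters (U). The two
hybridize antiparallel -- the PNA N-terminus faces the RNA 3' end -- so an
anti-miR chain reads as the reverse complement of the miRNA stretch it blocks.
U and T are treated as equivalent for pairing.

Coordinates are 0-based half-open internally; every user-facing report uses
1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Alphabet",
    "PairClass",
    "CTermCap",
    "NucleicSeq",
    "PNAChain",
    "Conjugate",
    "AlphabetError",
    "ContractError",
    "reverse_complement",
    "to_rna",
    "to_dna",
    "base_pair_class",
]


class AlphabetError(ValueError):
    """A residue character is not part of the declared alphabet."""


class ContractError(ValueError):
    """An operation precondition was violated."""


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


class PairClass(str, Enum):
    """Duplex base-pair classes: Watson-Crick A:U(T), Watson-Crick G:C,
    G:U wobble, or no pair."""

    WC_AU = "WC_AU"
    WC_GC = "WC_GC"
    GU = "GU"
    NONE = "NONE"


class CTermCap(str, Enum):
    AMIDE = "amide"
    FREE_ACID = "free_acid"


_RNA_BASES = frozenset("ACGU")
_DNA_BASES = frozenset("ACGT")
_AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _validate_residues(residues: str, allowed: frozenset[str], what: str) -> str:
    residues = residues.upper()
    for i, ch in enumerate(residues):
        if ch not in allowed:
            raise AlphabetError(
                f"{what}: illegal character {ch!r} at position {i + 1} "
                f"(allowed: {''.join(sorted(allowed))})"
            )
    if not residues:
        raise AlphabetError(f"{what}: empty sequence")
    return residues


@dataclass(frozen=True)
class NucleicSeq:
    """A named RNA or DNA sequence, 5'->3'.

    Input is case-insensitive and normalized to uppercase. IUPAC ambiguity
    codes are rejected: pairing semantics must be unambiguous.
    """

    name: str
    residues: str
    alphabet: Alphabet = Alphabet.RNA

    def __post_init__(self) -> None:
        allowed = _RNA_BASES if self.alphabet is Alphabet.RNA else _DNA_BASES
        object.__setattr__(
            self, "residues", _validate_residues(self.residues, allowed, self.name or "sequence")
        )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]


@dataclass(frozen=True)
class PNAChain:
    """A PNA nucleobase chain written N-terminus -> C-terminus, DNA-lettered."""

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _validate_residues(self.bases, _DNA_BASES, "PNA chain"))

    def __len__(self) -> int:
        return len(self.bases)

    def as_rna(self, name: str = "pna") -> NucleicSeq:
        """The chain with T->U substitution, for pairing against RNA.

        Read N->C; against a 5'->3' RNA the duplex is antiparallel.
        """
        return NucleicSeq(name, self.bases.replace("T", "U"), Alphabet.RNA)


@dataclass(frozen=True)
class Conjugate:
    """A peptide-PNA conjugate: N-terminal carrier peptide, PNA chain,
    C-terminal spacer and cap.

    The canonical object of the method is H-R8-<18 bases>-Gly-NH2: an
    octaarginine delivery peptide, the anti-miR chain, a glycine spacer and a
    C-terminal amide. ``pna=None`` denotes a bare peptide (degenerate but
    mass-computable).
    """

    n_term_peptide: str
    pna: PNAChain | None
    c_term_spacer: str = ""
    c_term_cap: CTermCap = CTermCap.AMIDE

    def __post_init__(self) -> None:
        for label, aas in (("peptide", self.n_term_peptide), ("spacer", self.c_term_spacer)):
            up = aas.upper()
            for i, ch in enumerate(up):
                if ch not in _AA_CODES:
                    raise AlphabetError(
                        f"conjugate {label}: unknown amino-acid code {ch!r} at position {i + 1}"
                    )
            object.__setattr__(
                self, "n_term_peptide" if label == "peptide" else "c_term_spacer", up
            )


def reverse_complement(seq: NucleicSeq) -> NucleicSeq:
    """Reverse and base-complement, preserving the alphabet."""
    table = _RNA_COMPLEMENT if seq.alphabet is Alphabet.RNA else _DNA_COMPLEMENT
    return NucleicSeq(f"{seq.name}_rc", seq.residues.translate(table)[::-1], seq.alphabet)


def to_rna(seq: NucleicSeq) -> NucleicSeq:
    """T->U substitution; no-op if already RNA."""
    if seq.alphabet is Alphabet.RNA:
        return seq
    return NucleicSeq(seq.name, seq.residues.replace("T", "U"), Alphabet.RNA)


def to_dna(seq: NucleicSeq) -> NucleicSeq:
    """U->T substitution; no-op if already DNA."""
    if seq.alphabet is Alphabet.DNA:
        return seq
    return NucleicSeq(seq.name, seq.residues.replace("U", "T"), Alphabet.DNA)


def base_pair_class(b1: str, b2: str, allow_wobble: bool = False) -> PairClass:
    """Classify the pair formed by two bases in an antiparallel duplex.

    T is normalized to U before classification (PNA T pairs RNA A exactly as
    U would). G:U wobble is recognized only when ``allow_wobble`` is set --
    it is a legitimate pair in RNA:RNA duplexes but PNAs are screened on
    strict Watson-Crick pairing.
    """
    pair = set()
    for b in (b1, b2):
        b = b.upper().replace("T", "U")
        if b not in _RNA_BASES:
            raise AlphabetError(f"not a nucleobase: {b!r}")
        pair.add(b)
    if pair == {"A", "U"}:
        return PairClass.WC_AU
    if pair == {"C", "G"}:
        return PairClass.WC_GC
    if pair == {"G", "U"} and allow_wobble:
        return PairClass.GU
    return PairClass.NONE
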