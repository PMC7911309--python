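"""Molecular weights of peptide-PNA conjugates and ESI-MS charge series.

The conjugate mass model is strictly additive over residues:

    MW = sum(amino-acid residues) + sum(PNA residues)
         + N-terminal H + C-terminal cap (NH2 for amide, OH for free acid)

PNA residue compositions are derived from the N-(2-aminoethyl)glycine
backbone unit carrying a nucleobase-acetyl side chain: the backbone
contributes C6H9N2O2 per incorporated residue and the base its formula minus
the hydrogen lost at the linkage nitrogen. Amino-acid residue compositions
come from pyteomics. Average and monoisotopic masses are both supported and
every call states which it wants; printed "calculated MW" values for
conjugates of this kind are average-mass calculations.

Electrospray ionization observes multiply protonated species [M+nH]n+ at

    m/z(n) = (MW + n * m_H+) / n

with the proton (1.00728 Da) as the default charge carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from pyteomics.mass import Composition, calculate_mass, std_aa_comp

from .seqcore import Conjugate, ContractError, CTermCap

__all__ = [
    "MassTable",
    "MassResult",
    "DEFAULT_MASS_TABLE",
    "PROTON_MASS",
    "HYDROGEN_ATOM_MASS",
    "conjugate_mw",
    "esi_series",
    "conjugate_mass_result",
    "mass_equal_under_permutation",
]

PROTON_MASS = 1.00728  # Da, [M+nH]n+ charge carrier
HYDROGEN_ATOM_MASS = 1.00794  # Da, alternative neutral-H convention

# aeg-PNA backbone residue (-NH-CH2-CH2-N(COCH2-)-CH2-CO-) and the four
# nucleobases minus the H displaced by the acetyl linkage.
_PNA_BACKBONE = Composition(formula="C6H9N2O2")
_BASE_LESS_H = {
    "A": Composition(formula="C5H4N5"),  # adenin-9-yl
    "C": Composition(formula="C4H4N3O"),  # cytosin-1-yl
    "G": Composition(formula="C5H4N5O"),  # guanin-9-yl
    "T": Composition(formula="C5H5N2O2"),  # thymin-1-yl
}


def _default_pna_comp() -> dict[str, Composition]:
    return {b: _PNA_BACKBONE + comp for b, comp in _BASE_LESS_H.items()}


def _default_aa_comp() -> dict[str, Composition]:
    return {aa: std_aa_comp[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass(frozen=True)
class MassTable:
    """Residue compositions and terminal adjustments behind every mass.

    The table is data, not code: swap in alternative compositions (or a
    hydrogen-atom charge carrier) without touching the calculators.
    """

    pna_residues: dict[str, Composition] = field(default_factory=_default_pna_comp)
    aa_residues: dict[str, Composition] = field(default_factory=_default_aa_comp)
    n_term: Composition = field(default_factory=lambda: Composition(formula="H"))
    c_term_amide: Composition = field(default_factory=lambda: Composition(formula="NH2"))
    c_term_free_acid: Composition = field(default_factory=lambda: Composition(formula="OH"))
    proton_mass: float = PROTON_MASS

    def residue_mass(self, kind: Literal["pna", "aa"], code: str, average: bool) -> float:
        table = self.pna_residues if kind == "pna" else self.aa_residues
        if code not in table:
            raise ContractError(f"no mass for {kind} residue {code!r}")
        return calculate_mass(composition=table[code], average=average)


DEFAULT_MASS_TABLE = MassTable()

Mode = Literal["average", "monoisotopic"]


def conjugate_composition(conj: Conjugate, table: MassTable | None = None) -> Composition:
    """Total elemental composition of a conjugate."""
    table = table or DEFAULT_MASS_TABLE
    total = Composition(table.n_term)
    for aa in conj.n_term_peptide:
        if aa not in table.aa_residues:
            raise ContractError(f"no mass for amino-acid residue {aa!r}")
        total += table.aa_residues[aa]
    for b in conj.pna.bases if conj.pna is not None else "":
        if b not in table.pna_residues:
            raise ContractError(f"no mass for PNA residue {b!r}")
        total += table.pna_residues[b]
    for aa in conj.c_term_spacer:
        if aa not in table.aa_residues:
            raise ContractError(f"no mass for amino-acid residue {aa!r}")
        total += table.aa_residues[aa]
    total += (
        table.c_term_amide if conj.c_term_cap is CTermCap.AMIDE else table.c_term_free_acid
    )
    return total


def conjugate_mw(
    conj: Conjugate, table: MassTable | None = None, mode: Mode = "average"
) -> float:
    """Molecular weight of a conjugate (g/mol average, or Da monoisotopic)."""
    comp = conjugate_composition(conj, table)
    return calculate_mass(composition=comp, average=(mode == "average"))


def esi_series(
    mw: float, charges: list[int], table: MassTable | None = None
) -> list[tuple[int, float]]:
    """[M+nH]n+ m/z values for the requested charge states.

    No rounding is applied; round at presentation (2 decimals matches the
    usual reporting convention).
    """
    table = table or DEFAULT_MASS_TABLE
    series = []
    for n in charges:
        if n < 1:
            raise ContractError(f"charge state must be >= 1, got {n}")
        series.append((n, (mw + n * table.proton_mass) / n))
    return series


@dataclass(frozen=True)
class MassResult:
    """Average and monoisotopic mass plus the ESI charge-state series."""

    mw_avg: float
    mw_mono: float
    series: tuple[tuple[int, float], ...]


def conjugate_mass_result(
    conj: Conjugate, charges: list[int], table: MassTable | None = None
) -> MassResult:
    """One-call summary: both masses and the average-mass ESI series."""
    table = table or DEFAULT_MASS_TABLE
    avg = conjugate_mw(conj, table, "average")
    mono = conjugate_mw(conj, table, "monoisotopic")
    return MassResult(avg, mono, tuple(esi_series(avg, charges, table)))


def mass_equal_under_permutation(c1: Conjugate, c2: Conjugate) -> bool:
    """True iff the two conjugates are guaranteed mass-identical: same
    peptide, spacer and cap, and the same PNA base multiset.

    A scrambled control preserves base composition, so its conjugate mass is
    bit-identical to the parent's.
    """
    from collections import Counter

    return (
        c1.n_term_peptide == c2.n_term_peptide
        and c1.c_term_spacer == c2.c_term_spacer
        and c1.c_term_cap == c2.c_term_cap
        and Counter(c1.pna.bases if c1.pna else "") == Counter(c2.pna.bases if c2.pna else "")
    )
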