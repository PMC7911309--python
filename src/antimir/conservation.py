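"""Binding-site conservation across orthologous 3'-UTR segments.

Given a pre-built multiple alignment of orthologous UTR stretches (one row
per species, a designated reference row -- human, by convention), the profile
reports, for every alignment column, the fraction of non-reference rows whose
residue matches the reference. Gaps and ambiguity characters count as
mismatches. A binding-site interval is then summarized by the arithmetic
mean of its per-column identities.

Alignment construction itself is out of scope: rows arrive already aligned
(aligned FASTA or CLUSTAL via the io module).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import ContractError

__all__ = [
    "OrthologAlignment",
    "ConservationProfile",
    "column_identity",
    "site_conservation",
    "render_homology_bar",
]


@dataclass(frozen=True)
class OrthologAlignment:
    """Named aligned rows of equal length; gap character '-'.

    ``reference`` names the comparison baseline row (default: the first row).
    """

    rows: tuple[tuple[str, str], ...]
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ContractError("alignment has no rows")
        width = len(self.rows[0][1])
        if width < 1:
            raise ContractError("alignment has zero columns")
        for name, seq in self.rows:
            if len(seq) != width:
                raise ContractError(f"ragged alignment: row {name!r} has length {len(seq)}, expected {width}")
        names = [n for n, _ in self.rows]
        ref = self.reference if self.reference is not None else names[0]
        if ref not in names:
            raise ContractError(f"reference row {ref!r} not present")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(
            self, "rows", tuple((n, s.upper()) for n, s in self.rows)
        )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def reference_row(self) -> str:
        return dict(self.rows)[self.reference]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column identity fractions (to the reference), all in [0, 1]."""

    per_column_identity: tuple[float, ...]
    reference: str
    n_rows_compared: int


def column_identity(aln: OrthologAlignment) -> ConservationProfile:
    """Fraction of non-reference rows matching the reference at each column.

    A gap in either the reference or the compared row counts as a mismatch,
    as does any non-ACGTU character.
    """
    ref = aln.reference_row
    others = [s for n, s in aln.rows if n != aln.reference]
    if not others:
        raise ContractError("alignment needs at least one non-reference row")
    ncol = aln.n_columns
    fractions = []
    for c in range(ncol):
        rc = ref[c]
        if rc == "-" or rc not in "ACGTU":
            fractions.append(0.0)
            continue
        matches = sum(1 for s in others if s[c] == rc)
        fractions.append(matches / len(others))
    return ConservationProfile(tuple(fractions), aln.reference, len(others))


def site_conservation(profile: ConservationProfile, site: tuple[int, int]) -> float:
    """Mean per-column identity over a 1-based inclusive column interval."""
    lo, hi = site
    if not (1 <= lo <= hi <= len(profile.per_column_identity)):
        raise ContractError(f"site {site} outside alignment columns 1-{len(profile.per_column_identity)}")
    cols = profile.per_column_identity[lo - 1 : hi]
    return sum(cols) / len(cols)


_BAR_LEVELS = " .:-=+*#%@"


def render_homology_bar(profile: ConservationProfile, sites: list[tuple[int, int]] | None = None) -> str:
    """Text homology bar: one character per column, denser = more conserved;
    a second line underlines binding-site intervals."""
    bar = "".join(
        _BAR_LEVELS[min(int(f * (len(_BAR_LEVELS) - 1) + 0.5), len(_BAR_LEVELS) - 1)]
        for f in profile.per_column_identity
    )
    lines = [bar]
    if sites:
        marks = [" "] * len(profile.per_column_identity)
        for lo, hi in sites:
            for c in range(lo - 1, hi):
                marks[c] = "^"
        lines.append("".join(marks))
    return "\n".join(lines)
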