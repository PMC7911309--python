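"""Defined-formula utilities for downstream result tables.

Three small, exactly specified computations:

* fold-change bucketing of a miRNA expression table (treated/untreated
  ratios) into not-modulated / up-regulated / moderately down-regulated /
  strongly down-regulated classes, with a two-fold modulation threshold;
* the order-stable intersection of three identifier lists (the Venn-center
  question: which miRNA appears in every list?);
* normalization of a fluorescence quenching trace relative to the value at
  the moment of iodide addition, Fx(t) = ((Ft - Fo) / Fo) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import ContractError

__all__ = [
    "FoldChangeRecord",
    "FoldChangeBuckets",
    "FluorTrace",
    "classify_fold_changes",
    "common_to_all",
    "fx_normalize",
]

BUCKETS = ("not_modulated", "up", "down_mid", "down_high")


@dataclass(frozen=True)
class FoldChangeRecord:
    """One miRNA's fold change, as treated/untreated expression ratio (> 0)."""

    mirna_id: str
    fc: float

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ContractError(f"{self.mirna_id}: fold change must be positive, got {self.fc}")


@dataclass(frozen=True)
class FoldChangeBuckets:
    """Counts, member lists and fractions per modulation class."""

    counts: dict[str, int]
    members: dict[str, tuple[str, ...]]
    fractions: dict[str, float]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def classify_fold_changes(
    records: Iterable[FoldChangeRecord], threshold: float = 2.0, high: float = 3.0
) -> FoldChangeBuckets:
    """Bucket miRNAs by modulation magnitude.

    With fc = treated/untreated: ``up`` when fc >= threshold; down-regulated
    when 1/fc >= threshold, split into ``down_mid`` (1/fc in [threshold,
    high]) and ``down_high`` (1/fc > high); everything else
    ``not_modulated``. A fold change exactly at the modulation threshold
    counts as modulated. Buckets are disjoint and exhaustive; fractions sum
    to 1.
    """
    if not threshold > 1 or not high >= threshold:
        raise ContractError("need threshold > 1 and high >= threshold")
    members: dict[str, list[str]] = {b: [] for b in BUCKETS}
    n = 0
    for rec in records:
        n += 1
        if rec.fc >= threshold:
            bucket = "up"
        elif 1.0 / rec.fc >= threshold:
            bucket = "down_high" if 1.0 / rec.fc > high else "down_mid"
        else:
            bucket = "not_modulated"
        members[bucket].append(rec.mirna_id)
    if n == 0:
        raise ContractError("no records")
    counts = {b: len(members[b]) for b in BUCKETS}
    return FoldChangeBuckets(
        counts=counts,
        members={b: tuple(members[b]) for b in BUCKETS},
        fractions={b: counts[b] / n for b in BUCKETS},
    )


def common_to_all(*lists: Sequence[str]) -> list[str]:
    """Identifiers present in every list, in first-list order."""
    if not lists:
        return []
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    seen: set[str] = set()
    out = []
    for ident in lists[0]:
        if ident in common and ident not in seen:
            out.append(ident)
            seen.add(ident)
    return out


@dataclass(frozen=True)
class FluorTrace:
    """A fluorescence time course; ``t0_index`` marks iodide addition,
    defining the reference value Fo."""

    times: tuple[float, ...]
    F: tuple[float, ...]
    t0_index: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.F):
            raise ContractError("times and F must have equal length")
        if not (0 <= self.t0_index < len(self.F)):
            raise ContractError("t0_index out of range")


def fx_normalize(trace: FluorTrace) -> np.ndarray:
    """Signal variation relative to iodide addition:
    Fx(t) = ((Ft - Fo) / Fo) * 100. Zero at t0 by construction; invariant
    under rescaling the raw trace."""
    F = np.asarray(trace.F, dtype=float)
    Fo = F[trace.t0_index]
    if Fo == 0:
        raise ContractError("Fo (fluorescence at iodide addition) must be nonzero")
    return (F - Fo) / Fo * 100.0
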