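"""File formats, conjugate-descriptor parsing, and the synthetic fixture
generator.

Formats are deliberately few: FASTA for sequences, aligned FASTA / CLUSTAL
for ortholog blocks, TSV for tables, JSON for machine-readable twins.
Conjugates travel as text descriptors in the synthesis notation
``H-R8-TTTCGTTATTGCTCTTGA-Gly-NH2`` (R-run shorthand expanded, underscore /
markup variants like ``R_8_`` and ``NH_2_`` accepted).

The fixture generator emulates the study's input shapes with planted ground
truth: a miRNA, a UTR with an embedded complementary site, an ortholog
alignment with known per-row mutations, and a fold-change table drawn from
known bucket proportions. Every bundle is bit-reproducible from its spec.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .seqcore import (
    Alphabet,
    AlphabetError,
    Conjugate,
    ContractError,
    CTermCap,
    NucleicSeq,
    PNAChain,
    reverse_complement,
)
from .conservation import OrthologAlignment

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "parse_conjugate",
    "format_conjugate",
    "FixtureSpec",
    "FixtureBundle",
    "generate_fixtures",
    "write_fixtures",
]


class ParseError(ValueError):
    """A file or descriptor failed to parse; the message names the offender."""


def _detect_alphabet(residues: str) -> Alphabet:
    has_u = "U" in residues
    has_t = "T" in residues
    if has_u and has_t:
        raise ParseError("sequence mixes U and T")
    return Alphabet.RNA if has_u else Alphabet.DNA


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[NucleicSeq]:
    """Parse a FASTA file into NucleicSeq records.

    Names are the first whitespace-delimited header token; residues are
    uppercased. The alphabet is auto-detected per record (U -> RNA, else
    DNA) unless forced. Empty files, duplicate names and non-ACGTU
    characters are rejected with named errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    out: list[NucleicSeq] = []
    seen: set[str] = set()
    for rec in records:
        name = rec.id
        if name in seen:
            raise ParseError(f"{path}: duplicate record name {name!r}")
        seen.add(name)
        residues = str(rec.seq).upper()
        alph = alphabet or _detect_alphabet(residues)
        try:
            out.append(NucleicSeq(name, residues, alph))
        except AlphabetError as exc:
            raise ParseError(f"{path}: record {name!r}: {exc}") from exc
    return out


def write_fasta(seqs: list[NucleicSeq], path: str | Path, width: int = 60) -> None:
    """Write records with 60-column wrapped residues."""
    path = Path(path)
    with path.open("w") as fh:
        for seq in seqs:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta", reference: str | None = None) -> OrthologAlignment:
    """Read a pre-built ortholog alignment (aligned FASTA or CLUSTAL)."""
    aln = AlignIO.read(str(Path(path)), fmt)
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    return OrthologAlignment(rows, reference=reference)


# --- conjugate descriptors --------------------------------------------------

_SUBSCRIPT = re.compile(r"_(\d+)_")
_RUN = re.compile(r"^([A-Z])(\d+)$")


def _expand_runs(token: str) -> str:
    """R8 -> RRRRRRRR (any single-letter run shorthand)."""
    m = _RUN.match(token)
    if m:
        return m.group(1) * int(m.group(2))
    return token

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _as_peptide(token: str) -> str | None:
    """Interpret a descriptor token as a peptide; None if it is not one."""
    if not token:
        return ""
    if token.upper() in _AA3:
        return _AA3[token.upper()]
    expanded = _expand_runs(token)
    if expanded.isalpha() and expanded.isupper() and set(expanded) <= set("ACDEFGHIKLMNPQRSTVWY"):
        return expanded
    return None


def parse_conjugate(text: str) -> Conjugate:
    """Parse the synthesis notation H-<peptide>-<BASES>-<spacer>-NH2|OH.

    Peptide and spacer segments are optional; the peptide accepts run
    shorthand (R8) and three-letter codes (Gly); underscore markup (R_8_,
    NH_2_) is tolerated. The nucleobase segment is the longest ACGT-only
    token.
    """
    raw = text.strip()
    cleaned = _SUBSCRIPT.sub(r"\1", raw).replace(" ", "")
    tokens = cleaned.split("-")
    if len(tokens) < 3:
        raise ParseError(f"malformed conjugate descriptor {raw!r}")
    if tokens[0].upper() != "H":
        raise ParseError(f"descriptor must start with 'H-', got {tokens[0]!r}")
    cap_token = tokens[-1].upper()
    if cap_token == "NH2":
        cap = CTermCap.AMIDE
    elif cap_token == "OH":
        cap = CTermCap.FREE_ACID
    else:
        raise ParseError(f"descriptor must end with NH2 or OH, got {tokens[-1]!r}")
    inner = tokens[1:-1]
    # the PNA segment: the unique token made only of A/C/G/T
    base_idx = [i for i, tok in enumerate(inner) if tok and set(tok.upper()) <= set("ACGT")]
    if not base_idx:
        # report the first offending character of the longest candidate token
        worst = max(inner, key=len) if inner else ""
        bad = next((ch for ch in worst.upper() if ch not in "ACGT"), worst or "?")
        raise ParseError(f"no nucleobase segment found in {raw!r} (offending token near {bad!r})")
    bi = base_idx[-1] if len(base_idx) > 1 else base_idx[0]
    pna = PNAChain(inner[bi].upper())
    peptide = ""
    for tok in inner[:bi]:
        part = _as_peptide(tok)
        if part is None:
            raise ParseError(f"cannot read peptide token {tok!r} in {raw!r}")
        peptide += part
    spacer = ""
    for tok in inner[bi + 1 :]:
        part = _as_peptide(tok)
        if part is None:
            raise ParseError(f"cannot read spacer token {tok!r} in {raw!r}")
        spacer += part
    return Conjugate(peptide, pna, spacer, cap)


_AA1_TO_3 = {v: k.capitalize() for k, v in _AA3.items()}


def format_conjugate(conj: Conjugate) -> str:
    """Canonical descriptor text; parse(format(c)) == c.

    Homopolymeric peptides collapse to run shorthand (RRRRRRRR -> R8);
    single-residue spacers print as three-letter codes (G -> Gly).
    """
    parts = ["H"]
    if conj.n_term_peptide:
        pep = conj.n_term_peptide
        if len(set(pep)) == 1 and len(pep) > 1:
            parts.append(f"{pep[0]}{len(pep)}")
        else:
            parts.append(pep)
    parts.append(conj.pna.bases)
    if conj.c_term_spacer:
        sp = conj.c_term_spacer
        parts.append(_AA1_TO_3[sp] if len(sp) == 1 else sp)
    parts.append("NH2" if conj.c_term_cap is CTermCap.AMIDE else "OH")
    return "-".join(parts)


# --- synthetic fixtures -----------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic input bundle.

    ``site_position`` is the 1-based UTR position where the exact reverse
    complement of the miRNA is embedded. ``mutation_rate`` is the per-row,
    per-column substitution probability in the ortholog alignment.
    ``fc_proportions`` are the planted bucket proportions (not_modulated,
    up, down_mid, down_high).
    """

    seed: int = 7
    mirna_length: int = 23
    utr_length: int = 200
    site_position: int = 101
    n_ortholog_rows: int = 13
    ortholog_columns: int = 60
    mutation_rate: float = 0.05
    n_fold_changes: int = 1000
    fc_proportions: tuple[float, float, float, float] = (0.86, 0.04, 0.05, 0.05)

    def __post_init__(self) -> None:
        if self.site_position < 1 or self.site_position + self.mirna_length - 1 > self.utr_length:
            raise ContractError("embedded site falls outside the UTR")
        if abs(sum(self.fc_proportions) - 1.0) > 1e-9:
            raise ContractError("fc_proportions must sum to 1")


@dataclass(frozen=True)
class FixtureBundle:
    """In-memory fixture set plus the planted-truth manifest."""

    mirna: NucleicSeq
    utr: NucleicSeq
    orthologs: OrthologAlignment
    fold_changes: tuple  # of FoldChangeRecord
    truth: dict


_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, n: int, name: str) -> NucleicSeq:
    return NucleicSeq(name, "".join(rng.choice(_BASES, size=n)), Alphabet.RNA)


def generate_fixtures(spec: FixtureSpec) -> FixtureBundle:
    """Build the bundle; bit-identical output for a fixed spec."""
    from .analysis import BUCKETS, FoldChangeRecord

    rng = np.random.default_rng(spec.seed)

    mirna = _random_rna(rng, spec.mirna_length, "mir-synth")
    utr_res = list("".join(rng.choice(_BASES, size=spec.utr_length)))
    site = reverse_complement(mirna).residues
    p0 = spec.site_position - 1
    utr_res[p0 : p0 + len(site)] = site
    utr = NucleicSeq("utr-synth", "".join(utr_res), Alphabet.RNA)

    ref = "".join(rng.choice(_BASES, size=spec.ortholog_columns))
    rows = [("human", ref)]
    mutations: dict[str, list[int]] = {}
    for r in range(1, spec.n_ortholog_rows):
        name = f"species_{r:02d}"
        muts = []
        row = list(ref)
        for c in range(spec.ortholog_columns):
            if rng.random() < spec.mutation_rate:
                row[c] = rng.choice([b for b in "ACGU" if b != ref[c]])
                muts.append(c + 1)
        rows.append((name, "".join(row)))
        mutations[name] = muts

    bucket_of = rng.choice(len(BUCKETS), size=spec.n_fold_changes, p=spec.fc_proportions)
    fc_records = []
    planted_counts = {b: 0 for b in BUCKETS}
    for i, bi in enumerate(bucket_of):
        bucket = BUCKETS[bi]
        planted_counts[bucket] += 1
        if bucket == "not_modulated":
            fc = float(rng.uniform(0.55, 1.85))
        elif bucket == "up":
            fc = float(rng.uniform(2.05, 6.0))
        elif bucket == "down_mid":
            fc = 1.0 / float(rng.uniform(2.05, 2.95))
        else:
            fc = 1.0 / float(rng.uniform(3.05, 8.0))
        fc_records.append(FoldChangeRecord(f"mir-synth-{i:04d}", fc))

    truth = {
        "seed": spec.seed,
        "site_interval": [spec.site_position, spec.site_position + spec.mirna_length - 1],
        "mutation_positions": mutations,
        "planted_bucket_counts": planted_counts,
        "planted_proportions": list(spec.fc_proportions),
    }
    return FixtureBundle(mirna, utr, OrthologAlignment(tuple(rows)), tuple(fc_records), truth)


def write_fixtures(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Materialize a bundle: FASTA files, fold-change TSV and a JSON manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna": outdir / "mirna.fa",
        "utr": outdir / "utr.fa",
        "orthologs": outdir / "orthologs.afa",
        "fold_changes": outdir / "fold_changes.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta([bundle.mirna], paths["mirna"])
    write_fasta([bundle.utr], paths["utr"])
    with paths["orthologs"].open("w") as fh:
        for name, seq in bundle.orthologs.rows:
            fh.write(f">{name}\n{seq}\n")
    with paths["fold_changes"].open("w") as fh:
        fh.write("mirna_id\tfc\n")
        for rec in bundle.fold_changes:
            fh.write(f"{rec.mirna_id}\t{rec.fc:.6g}\n")
    with paths["truth"].open("w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
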