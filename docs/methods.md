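# Methods

## Anti-miR design model

An anti-miR PNA candidate is defined entirely by a window of the mature
miRNA: the chain is the T-lettered reverse complement of the window, written
N-terminus to C-terminus, so that the duplex with the miRNA is antiparallel
(PNA N-terminus opposite the RNA 3′ end). Enumeration slides a fixed-length
window over the miRNA (L − length + 1 candidates for an L-nt miRNA) and
screens each candidate on four criteria:

- **length** — default 18 bases, a practical optimum between affinity and
  synthesis yield at scale;
- **seed coverage** — the window must contain miRNA nucleotides 2–8
  (1-based). The seed is the standard definition of the target-recognition
  core; a candidate that misses it can bind without blocking function;
- **self-complementarity** — the longest contiguous Watson–Crick run of the
  chain against a second copy of itself, scanned exhaustively over all
  relative offsets, in both antiparallel (reversed copy) and parallel
  (unreversed copy) orientation. PNA:PNA duplexes form in both geometries,
  which is why both are screened. The default pass threshold is a longest
  run ≤ 3; this is a declared convention — it is a design-screen default,
  not a measured stability boundary;
- **off-target runs** — for each supplied transcript, the longest contiguous
  stretch of the chain whose exact base-wise complement occurs in the
  transcript (antiparallel, i.e. against the reversed transcript) or in the
  transcript as written (parallel). The scan is an exact O(n·m) longest
  common-complementary-substring dynamic program with a default pass
  threshold of 12. An exact scan was chosen over a heuristic
  similarity search because it is deterministic and dependency-free at these
  problem sizes; candidates can still be exported as FASTA
  (`design --fasta-out`) for an external BLAST screen.

Thresholds are all parameters of `DesignCriteria`; the defaults are the
package's own operationalization of the qualitative criteria ("lack of
self-complementarity", "minimal complementary length").

The octaarginine carrier and glycine spacer are conjugate metadata, attached
at mass-calculation/export time: delivery chemistry does not enter sequence
screening.

## Scrambled controls

A control must abolish hybridization while keeping everything else equal —
including conjugate mass. The generator permutes the bases at exactly
`n_changes` positions (default 4): it draws positions and a permutation from
a seeded generator, rejects draws in which any selected position keeps its
original letter (so the Hamming distance is exactly `n_changes` and the base
multiset is untouched), and, when the target miRNA is supplied, rejects
candidates whose longest residual complementary run against it exceeds a
threshold (default 8). Sampling is bounded (default 10,000 attempts) and
deterministic per seed; homopolymers and other infeasible inputs raise an
explicit infeasibility error. Because only positions are permuted, the
control's conjugate mass is bit-identical to the parent's — a cross-check
the mass module exposes as `mass_equal_under_permutation`.

## Duplex model and site finding

Two complementary views are provided, because "how complementary is the
miRNA to this site" and "where is the best site" are different questions:

- `pair_gapless` tests query position i against site position L−1−i and
  tallies A:U, G:C and G:U bonds; `percent_complementarity` is
  n_paired / query_len, reported as the exact fraction (a 20-of-23 duplex is
  0.8696; figures rounded to 86.7% in the literature correspond to the same
  20/23 count).
- `find_best_site` finds the best intermolecular antiparallel duplex of a
  short strand inside a long one by a fit-style dynamic program over the
  reversed target: additive pair rewards (defaults G:C +3, A:U +2, G:U +1,
  mismatch 0), affine bulge penalties (open −4, extend −2), free leading and
  trailing target. This is a deliberate simplification of free-energy
  hybridization tools: it preserves the algorithmic contract (best-fitting
  site of a short strand in a long one, no intramolecular structure) without
  claiming thermodynamic equivalence, and all parameters are configurable
  (`DuplexScoring`). G:U wobble is on by default for RNA:RNA duplexes and
  off for PNA queries (`PNA_SCORING`), which are evaluated strict
  Watson–Crick.

Determinism and ties: equal-scoring sites resolve to the smallest target
start coordinate. Top-k sites are greedy non-overlapping: the best site is
accepted and the search recurses on the target stretches on either side of
it. With `allow_gaps=False` the search reduces to exhaustive gapless window
scanning, which is also the form verified against a brute-force oracle in
the tests. With gaps enabled, a hit's score equals the re-scoring of its
pairing map (pair rewards plus one affine penalty per inter-pair bulge);
the property suite checks this on random instances.

## Conservation scoring

Input is a pre-built alignment of orthologous UTR segments (aligned FASTA or
CLUSTAL); alignment construction is out of scope. The profile is per-column
identity **to the reference row** (human by convention, first row by
default): the fraction of non-reference rows whose character equals the
reference's, with gaps and ambiguity characters counting as mismatches. A
binding site's conservation is the arithmetic mean of its columns'
identities. To-reference identity (rather than column majority or a
substitution-model score) is this package's declared convention: it directly
answers "how faithfully do other species preserve the human site".

## Conjugate masses and ESI series

Masses are strictly residue-additive:

    MW = Σ amino-acid residues + Σ PNA residues + H (N-term) + cap (C-term)

with NH2 for the amide cap and OH for the free acid. PNA residue
compositions are derived from the aeg backbone unit (C6H9N2O2 per
incorporated residue) plus the nucleobase minus the hydrogen displaced by
the acetyl linkage, giving average residue masses A 275.27, C 251.25,
G 291.27, T 266.26. Amino-acid compositions come from pyteomics; the whole
table (`MassTable`) is data, swappable without touching the calculators.
Average vs monoisotopic is explicit in every call; reported "calculated MW"
values for conjugates of this kind are average-mass figures.

Computed MWs for the four canonical conjugates sit a consistent ≈0.13 Da
below the values reported for them. The mass table behind those reported
figures is not published; the offset is constant across all four conjugates
and well inside the ±0.5 Da agreement the package's tests require, so no
attempt is made to reverse-engineer it.

ESI charge states are m/z(n) = (MW + n·m_carrier)/n with the proton
(1.00728 Da) as default carrier; a hydrogen-atom mass (1.00794) is available
since reporting conventions vary. Values are exact internally and rounded to
2 decimals only at presentation.

## Expression-table utilities

Fold changes are treated/untreated ratios. With threshold τ = 2 and high
cut h = 3: up-regulated when fc ≥ τ; down-regulated when 1/fc ≥ τ, split
into moderate (1/fc ∈ [τ, h]) and strong (1/fc > h); otherwise not
modulated. A value exactly at the modulation threshold counts as modulated.
The ratio direction (treated/untreated) and the boundary rules are declared
conventions, both configurable. `common_to_all` returns the identifiers
present in every list, ordered by the first list. `fx_normalize` implements
Fx(t) = 100·(Ft − Fo)/Fo with Fo the fluorescence at iodide addition; it is
invariant under rescaling the raw trace and requires Fo ≠ 0.

## Synthetic fixtures

`generate_fixtures` emulates the input shapes the toolkit consumes, with the
ground truth recorded in a manifest: a random miRNA (23 nt), a UTR (200 nt)
with the miRNA's exact reverse complement embedded at a known 1-based
position (101), a 13-row × 60-column ortholog alignment with per-row
mutations at rate 0.05 and recorded positions, and a 1000-row fold-change
table drawn from planted bucket proportions (0.86 / 0.04 / 0.05 / 0.05 for
not-modulated / up / moderate-down / strong-down, fold changes sampled away
from bucket boundaries). All sampling flows from one seeded generator;
bundles are bit-identical per seed.

What the fixtures do not emulate: real UTRs are not uniform-random (they
have composition bias, repeats, and structure that create near-complementary
decoys), real ortholog alignments contain indels, and real expression tables
have estimation noise on each fold change rather than exactly-known bucket
membership. Passing the planted-truth tests therefore demonstrates
correctness of the algorithms, not performance on genomic data; the
off-target and site-finding screens in particular will face much harder
near-miss structure in real transcriptomes.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open internally, 1-based inclusive in every
  user-facing report.
- A duplex with no complementary positions is valid (empty pairing map,
  score 0); `percent_complementarity` rejects zero-length queries.
- `Conjugate.pna = None` denotes a bare peptide; the fully degenerate
  conjugate (no residues at all, free acid) evaluates to the mass of water,
  as the additive model requires.
- Scramble feasibility is checked eagerly for homopolymers; all other
  infeasibility surfaces as a bounded-attempts error.
- Problem sizes in the test and acceptance suites (200 random site-finder
  instances with targets ≤ 40 nt; 100 off-target transcripts of 500 nt;
  n = 1000 fold-change tables) were chosen so that the brute-force oracles
  remain exhaustive and exact.

## Known limitations

- The duplex scorer is not a thermodynamic model: no stacking, loop or
  temperature terms, no significance estimates for hits.
- The off-target scan is exact-complementarity only; it does not model
  mismatched or G:U-containing off-target hybridization.
- Conservation is to-reference identity; it does not weight by phylogeny or
  substitution rates.
- The mass model covers the 20 standard amino acids and the four canonical
  nucleobases; modified bases and backbone variants need a custom
  `MassTable`.
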