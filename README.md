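# antimir

Design and desk characterization of anti-miRNA peptide nucleic acids (PNAs).

A PNA is a DNA mimic with an uncharged N-(2-aminoethyl)glycine backbone that
hybridizes RNA by Watson–Crick pairing. An anti-miR PNA is the reverse
complement of a stretch of a mature miRNA: delivered into cells (typically as
an N-terminal octaarginine, "R8", conjugate) it sequesters the miRNA and
de-represses its targets. This package implements the computational half of
that workflow, for researchers designing anti-miR oligomers and matched
controls:

- **candidate enumeration** — every sliding-window anti-miR of fixed length
  (default 18) against a mature miRNA, screened on seed coverage (miRNA nt
  2–8), self-complementarity in antiparallel and parallel orientation, and
  longest exact complementary run in non-target transcripts;
- **scrambled controls** — seeded, composition-preserving permutation of
  exactly *n* nucleobase positions (default 4), verified to no longer
  hybridize the miRNA; same composition means the control conjugate has
  exactly the parent's mass;
- **duplex site finding** — the best antiparallel intermolecular duplex of a
  short strand within a long one (miRNA in a 3′-UTR), by dynamic programming
  with additive pair rewards (G:C > A:U > G:U) and affine bulge penalties,
  plus gapless pairing maps with A:U / G:C / G:U bond counts and percent
  complementarity;
- **conservation scoring** — per-column identity of orthologous UTR
  alignments against a reference row, and mean identity over binding-site
  intervals;
- **conjugate mass calculation** — average/monoisotopic MW of
  peptide–PNA conjugates from residue elemental compositions, and the
  electrospray charge series m/z(n) = (MW + n·m_H+)/n;
- **expression-table utilities** — two-fold-change bucketing of miRNA
  expression tables, three-list intersections, and fluorescence-trace
  normalization Fx(t) = 100·(Ft − Fo)/Fo.

## Worked example

Mass of the canonical conjugate H-R8-TTTCGTTATTGCTCTTGA-Gly-NH2 (an
octaarginine carrier, the 18-base anti-miR-335-5p chain, a glycine spacer,
C-terminal amide) and its ESI charge states:

```
$ antimir mass --conjugate "H-R8-TTTCGTTATTGCTCTTGA-Gly-NH2" --charges 5-9
# MW (average): 6164.17
charge  mz
5       1233.84
6       1028.37
7       881.6
8       771.53
9       685.91
```

The MW is the residue-additive average mass in g/mol; each m/z row is the
multiply protonated ion [M+nH]n+ observed in electrospray. Candidate
enumeration against the mature miRNA (FASTA input):

```
$ antimir design --mirna mir335.fa
candidate           mirna_window  seed_covered  self_comp_antiparallel  self_comp_parallel  max_offtarget_run  passes_all
TTTCGTTATTGCTCTTGA  1-18          True          2                       2                   0                  True
TTTTCGTTATTGCTCTTG  2-19          True          2                       2                   0                  True
TTTTTCGTTATTGCTCTT  3-20          False         2                       2                   0                  False
...
```

Each row is one sliding window: the candidate chain (N→C, the T-lettered
reverse complement of the window), whether the window covers the miRNA seed
(nt 2–8), the longest self-pairing runs in both orientations, and the
longest complementary run found in the supplied transcripts. A matched
scrambled control, deterministic per seed:

```
$ antimir --seed 11 scramble --pna TTTCGTTATTGCTCTTGA --verify-vs mir335.fa
{"control": "TTTCTTTAGTCGTCTTGA", "changed_positions": [5, 9, 11, 12],
 "hamming": 4, "residual_run": 6, "attempts": 6}
```

The control has the same base multiset as the parent (hence an identical
conjugate mass), differs at exactly four positions, and its longest residual
complementary run against the miRNA is 6 — too short for stable
hybridization. Library use mirrors the CLI
(`antimir.enumerate_candidates`, `antimir.make_scrambled_control`,
`antimir.find_best_site`, `antimir.conjugate_mw`, ...); see `docs/methods.md`
for the models and parameter choices.

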