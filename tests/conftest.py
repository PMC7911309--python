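import pytest

from antimir import NucleicSeq, PNAChain, reverse_complement, to_rna

# the four synthesized conjugates and their reported average MWs (g/mol)
CONJUGATES = {
    "a335": ("H-R8-TTTCGTTATTGCTCTTGA-Gly-NH2", 6164.30),
    "a335-MUT": ("H-R8-TTTAGTTCTTGCGCTTTA-Gly-NH2", 6164.30),
    "a96": ("H-R8-AAATGTGCTAGTGCCAAA-Gly-NH2", 6234.36),
    "a183": ("H-R8-AATTCTACCAGTGCCATA-Gly-NH2", 6145.31),
}

PNA_A335 = "TTTCGTTATTGCTCTTGA"
PNA_A335_MUT = "TTTAGTTCTTGCGCTTTA"


@pytest.fixture
def pna_a335():
    return PNAChain(PNA_A335)


@pytest.fixture
def pna_a335_mut():
    return PNAChain(PNA_A335_MUT)


@pytest.fixture
def mir335_site(pna_a335):
    """The 18-nt miRNA stretch the anti-miR blocks: by construction the
    reverse complement of the chain, RNA-lettered, 5'->3'."""
    return reverse_complement(pna_a335.as_rna("a335"))


@pytest.fixture
def mir335(pna_a335):
    """A full-length 23-nt mature miRNA: the blocked 18-nt stretch plus the
    native 3' tail."""
    head = to_rna(reverse_complement(NucleicSeq("head", PNA_A335, "DNA")))
    return NucleicSeq("miR-335-5p", head.residues + "AAUGU")
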