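import pytest
from hypothesis import settings

from mitocomp.alignment import CodonAlignment
from mitocomp.codes import genetic_code

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def code5():
    return genetic_code(5)


@pytest.fixture(scope="session")
def code1():
    return genetic_code(1)


def codon_alignment_from(seq1: str, seq2: str, code, gene: str = "g") -> CodonAlignment:
    """Build a gap-free codon alignment directly from two equal-length
    CDS, dropping stop-codon columns (e.g. the terminator)."""
    cs1 = [seq1[i:i + 3] for i in range(0, len(seq1) - len(seq1) % 3, 3)]
    cs2 = [seq2[i:i + 3] for i in range(0, len(seq2) - len(seq2) % 3, 3)]
    cols = [(a, b) for a, b in zip(cs1, cs2)
            if not (code.is_stop(a) or code.is_stop(b)) and "N" not in a + b]
    return CodonAlignment(gene, tuple(a for a, _ in cols),
                          tuple(b for _, b in cols), ("", ""))


@pytest.fixture(scope="session")
def make_caln():
    return codon_alignment_from
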