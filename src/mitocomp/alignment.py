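"""Protein-guided codon alignment for pairwise Ka/Ks estimation.

Homologous coding sequences are aligned at the protein level (global
affine-gap alignment, BLOSUM62, gap open 10 / extend 1) and the aligned
residues are then replaced by their source codons.  Columns containing a
gap or an N are dropped before substitution counting, which is the
standard preparation for pairwise dN/dS estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .codes import GeneticCode, genetic_code
from .genomes import translate


@dataclass(frozen=True)
class AlignmentScoring:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_proteins(p1: str, p2: str,
                   scoring: AlignmentScoring | None = None) -> tuple[str, str]:
    """Globally align two protein sequences; returns the gapped pair.

    Ties between optimal alignments are broken deterministically by
    taking the first alignment in the aligner's enumeration order, which
    prefers substitution columns over gaps at equal score.
    """
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    scoring = scoring or AlignmentScoring()
    p1 = p1.replace("*", "X")
    p2 = p2.replace("*", "X")
    aln = _aligner(scoring).align(p1, p2)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


@dataclass(frozen=True)
class CodonAlignment:
    """Gap- and N-free aligned codon columns for one gene pair."""

    gene: str
    codons1: tuple[str, ...]
    codons2: tuple[str, ...]
    aligned_proteins: tuple[str, str]
    dropped_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("aligned codon rows differ in length")
        if len(self.codons1) < 1:
            raise ValueError("empty codon alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)

    def pairs(self):
        return zip(self.codons1, self.codons2)


def back_translate_alignment(aligned: tuple[str, str], cds1: str, cds2: str,
                             code: GeneticCode | int = 5,
                             gene: str = "") -> CodonAlignment:
    """Replace aligned residues by their source codons.

    Each protein must be the translation of its CDS (trailing stop
    ignored); a mismatch raises an error naming the first offending
    residue.  Gap columns and columns with N-containing codons are
    dropped and counted.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    a1, a2 = aligned
    cods1, cods2, dropped = [], [], 0
    idx1 = idx2 = 0
    for col, (r1, r2) in enumerate(zip(a1, a2)):
        c1 = cds1[3 * idx1:3 * idx1 + 3] if r1 != "-" else None
        c2 = cds2[3 * idx2:3 * idx2 + 3] if r2 != "-" else None
        for which, r, c, cds, idx in (("first", r1, c1, cds1, idx1),
                                      ("second", r2, c2, cds2, idx2)):
            if r == "-":
                continue
            if c is None or len(c) < 3:
                raise ValueError(
                    f"{which} protein longer than its CDS at column {col}")
            aa = "X" if "N" in c else code.aa(c)
            if aa == "*":
                aa = "X"  # align_proteins masks stops the same way
            if aa != r and r != "X":
                raise ValueError(
                    f"{which} protein residue {r!r} at column {col} does not "
                    f"match codon {c!r}")
        if r1 != "-":
            idx1 += 1
        if r2 != "-":
            idx2 += 1
        if r1 == "-" or r2 == "-" or "N" in c1 or "N" in c2:
            dropped += 1
            continue
        cods1.append(c1)
        cods2.append(c2)
    return CodonAlignment(gene, tuple(cods1), tuple(cods2), (a1, a2), dropped)


def codon_align(cds1: str, cds2: str, code: GeneticCode | int = 5,
                gene: str = "", scoring: AlignmentScoring | None = None
                ) -> CodonAlignment:
    """Protein-align two CDS and back-translate to codon columns."""
    if isinstance(code, int):
        code = genetic_code(code)

    def prot(cds: str) -> str:
        p = translate(cds, code)
        return p[:-1] if p.endswith("*") else p

    p1, p2 = prot(cds1), prot(cds2)
    return back_translate_alignment(align_proteins(p1, p2, scoring),
                                    cds1, cds2, code, gene=gene)
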