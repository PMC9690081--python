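"""Published reference tables for the two Ruditapes mitogenomes.

These are the printed comparison surfaces this package reproduces: the
per-codon counts and RSCU values of the protein-coding genes of
*Ruditapes philippinarum* (GenBank MZ675529, 22,706 bp) and
*R. variegatus* (MZ675530, 20,997 bp), the per-gene organization table
(length, start/stop codon, strand), whole-genome composition rows, and
the short-code legend used for gene-order comparison figures.

Codon keys are RNA (U) exactly as printed; :func:`mitocomp.codes.dna`
converts them.  The counts are *inputs* to the RSCU arithmetic here —
nothing in this module is computed.
"""

from __future__ import annotations

RPHIL = "R_philippinarum"
RVAR = "R_variegatus"

ACCESSIONS = {RPHIL: "MZ675529", RVAR: "MZ675530"}

#: Printed codon counts of the PCG set, stop codons (UAA/UAG) excluded.
CODON_COUNTS: dict[str, dict[str, int]] = {
    RPHIL: {
        "UUU": 430, "UUC": 63, "UUA": 430, "UUG": 116,
        "CUU": 104, "CUC": 2, "CUA": 55, "CUG": 12,
        "AUU": 239, "AUC": 29, "AUA": 253, "AUG": 79,
        "GUU": 238, "GUC": 25, "GUA": 195, "GUG": 59,
        "UCU": 141, "UCC": 12, "UCA": 46, "UCG": 12,
        "CCU": 82, "CCC": 11, "CCA": 42, "CCG": 11,
        "ACU": 104, "ACC": 6, "ACA": 44, "ACG": 11,
        "GCU": 129, "GCC": 11, "GCA": 40, "GCG": 9,
        "UAU": 171, "UAC": 36, "CAU": 73, "CAC": 7,
        "CAA": 38, "CAG": 22, "AAU": 153, "AAC": 25,
        "AAA": 138, "AAG": 53, "GAU": 99, "GAC": 24,
        "GAA": 91, "GAG": 95, "UGU": 105, "UGC": 16,
        "UGA": 65, "UGG": 72, "CGU": 35, "CGC": 0,
        "CGA": 30, "CGG": 14, "AGU": 112, "AGC": 16,
        "AGA": 154, "AGG": 92, "GGU": 180, "GGC": 12,
        "GGA": 90, "GGG": 131,
    },
    RVAR: {
        "UUU": 324, "UUC": 61, "UUA": 265, "UUG": 139,
        "CUU": 39, "CUC": 7, "CUA": 43, "CUG": 30,
        "AUU": 174, "AUC": 25, "AUA": 151, "AUG": 98,
        "GUU": 154, "GUC": 20, "GUA": 134, "GUG": 127,
        "UCU": 68, "UCC": 10, "UCA": 34, "UCG": 32,
        "CCU": 66, "CCC": 8, "CCA": 35, "CCG": 15,
        "ACU": 57, "ACC": 7, "ACA": 30, "ACG": 24,
        "GCU": 103, "GCC": 19, "GCA": 36, "GCG": 37,
        "UAU": 140, "UAC": 40, "CAU": 46, "CAC": 16,
        "CAA": 38, "CAG": 23, "AAU": 72, "AAC": 27,
        "AAA": 71, "AAG": 63, "GAU": 77, "GAC": 18,
        "GAA": 66, "GAG": 74, "UGU": 88, "UGC": 22,
        "UGA": 39, "UGG": 65, "CGU": 30, "CGC": 3,
        "CGA": 18, "CGG": 29, "AGU": 62, "AGC": 19,
        "AGA": 90, "AGG": 121, "GGU": 98, "GGC": 17,
        "GGA": 88, "GGG": 149,
    },
}

#: Printed RSCU values (2 dp) matching CODON_COUNTS row for row.
PUBLISHED_RSCU: dict[str, dict[str, float]] = {
    RPHIL: {
        "UUU": 1.74, "UUC": 0.26, "UUA": 3.59, "UUG": 0.97,
        "CUU": 0.87, "CUC": 0.02, "CUA": 0.46, "CUG": 0.10,
        "AUU": 1.38, "AUC": 0.17, "AUA": 1.46, "AUG": 1.00,
        "GUU": 1.84, "GUC": 0.19, "GUA": 1.51, "GUG": 0.46,
        "UCU": 2.50, "UCC": 0.21, "UCA": 0.81, "UCG": 0.21,
        "CCU": 2.25, "CCC": 0.30, "CCA": 1.15, "CCG": 0.30,
        "ACU": 2.52, "ACC": 0.15, "ACA": 1.07, "ACG": 0.27,
        "GCU": 2.73, "GCC": 0.23, "GCA": 0.85, "GCG": 0.19,
        "UAU": 1.65, "UAC": 0.35, "CAU": 1.83, "CAC": 0.17,
        "CAA": 1.27, "CAG": 0.73, "AAU": 1.72, "AAC": 0.28,
        "AAA": 1.45, "AAG": 0.55, "GAU": 1.61, "GAC": 0.39,
        "GAA": 0.98, "GAG": 1.02, "UGU": 1.74, "UGC": 0.26,
        "UGA": 3.00, "UGG": 1.00, "CGU": 0.65, "CGC": 0.00,
        "CGA": 0.55, "CGG": 0.26, "AGU": 1.98, "AGC": 0.28,
        "AGA": 2.84, "AGG": 1.70, "GGU": 1.74, "GGC": 0.12,
        "GGA": 0.87, "GGG": 1.27,
    },
    RVAR: {
        "UUU": 1.68, "UUC": 0.32, "UUA": 3.04, "UUG": 1.59,
        "CUU": 0.45, "CUC": 0.08, "CUA": 0.49, "CUG": 0.34,
        "AUU": 1.49, "AUC": 0.21, "AUA": 1.29, "AUG": 1.00,
        "GUU": 1.42, "GUC": 0.18, "GUA": 1.23, "GUG": 1.17,
        "UCU": 1.81, "UCC": 0.27, "UCA": 0.91, "UCG": 0.85,
        "CCU": 2.13, "CCC": 0.26, "CCA": 1.13, "CCG": 0.48,
        "ACU": 1.93, "ACC": 0.24, "ACA": 1.02, "ACG": 0.81,
        "GCU": 2.11, "GCC": 0.39, "GCA": 0.74, "GCG": 0.76,
        "UAU": 1.56, "UAC": 0.44, "CAU": 1.48, "CAC": 0.52,
        "CAA": 1.25, "CAG": 0.75, "AAU": 1.45, "AAC": 0.55,
        "AAA": 1.06, "AAG": 0.94, "GAU": 1.62, "GAC": 0.38,
        "GAA": 0.94, "GAG": 1.06, "UGU": 1.60, "UGC": 0.40,
        "UGA": 3.00, "UGG": 1.00, "CGU": 0.62, "CGC": 0.06,
        "CGA": 0.37, "CGG": 0.60, "AGU": 1.65, "AGC": 0.51,
        "AGA": 1.86, "AGG": 2.49, "GGU": 1.11, "GGC": 0.19,
        "GGA": 1.00, "GGG": 1.69,
    },
}

#: Rows whose printed RSCU follows the zeroed-stop-family quirk (UGA sits
#: in the standard-code stop family whose UAA/UAG counts are zero, giving
#: RSCU(UGA)=3 and RSCU(UGG)=1 exactly); reproduced, but flagged.
DIALECT_FLAGGED_CODONS = ("UGA", "UGG")

#: Printed totals of codons in the PCG sets, stop codons excluded.
TOTAL_CODONS = {RPHIL: 5189, RVAR: 4081}

#: Per-gene organization: (gene, length bp, start codon, stop codon, strand).
PCG_PROFILES: dict[str, tuple[tuple[str, int, str, str, str], ...]] = {
    RPHIL: (
        ("COX1", 1719, "ATA", "TAG", "+"),
        ("ND1", 930, "ATA", "TAA", "+"),
        ("ND2", 1035, "ATT", "TAG", "+"),
        ("ND4L", 282, "ATT", "TAA", "+"),
        ("COX2", 1995, "ATC", "TAA", "+"),
        ("COX2", 1608, "ATA", "TAA", "+"),
        ("CYTB", 1224, "ATT", "TAA", "+"),
        ("ATP8", 120, "ATT", "TAG", "+"),
        ("ND4", 1359, "ATG", "TAA", "+"),
        ("ATP6", 738, "ATA", "TAG", "+"),
        ("ND3", 405, "GTG", "TAA", "+"),
        ("ND5", 1665, "TTG", "TAA", "+"),
        ("ND6", 510, "TTG", "TAA", "+"),
        ("COX3", 864, "ATT", "TAA", "+"),
    ),
    RVAR: (
        ("COX1", 1758, "GTG", "TAG", "+"),
        ("ND1", 933, "ATG", "TAG", "+"),
        ("ND2", 1029, "ATG", "TAG", "+"),
        ("COX2", 1416, "TTG", "TAG", "+"),
        ("CYTB", 1239, "ATT", "TAA", "+"),
        ("ATP8", 120, "TTG", "TAA", "+"),
        ("ND4", 1356, "ATG", "TAA", "+"),
        ("ATP6", 735, "ATG", "TAG", "+"),
        ("ND3", 405, "ATG", "TAA", "+"),
        ("ND5", 1704, "GTG", "TAA", "+"),
        ("ND4L", 279, "ATG", "TAG", "+"),
        ("ND6", 522, "ATG", "TAG", "+"),
        ("COX3", 882, "ATT", "TAA", "+"),
    ),
}

#: Printed PCG length totals (bp) and genome sizes (bp).
TOTAL_PCG_BP = {RPHIL: 14454, RVAR: 12378}
GENOME_SIZE_BP = {RPHIL: 22706, RVAR: 20997}

#: Whole-genome composition rows: A%, C%, G%, T%, GC%.
GENOME_COMPOSITION = {
    RPHIL: {"A%": 30.2, "C%": 9.8, "G%": 20.5, "T%": 39.6, "GC%": 30.3},
    RVAR: {"A%": 28.1, "C%": 10.7, "G%": 25.7, "T%": 35.5, "GC%": 36.4},
}

#: Published PCG proportion of the R. philippinarum genome (%).
PCG_PROPORTION_RPHIL = 63.66

#: Short-code legend for gene-order comparison (lowercase = tRNAs,
#: digits = PCGs, uppercase = rRNAs + ATP genes).
SHORT_CODES: dict[str, str] = {
    "a": "trnL-TAG", "b": "trnY-ATA", "c": "trnC-GCA", "d": "trnP-AGG",
    "e": "trnI-GAT", "f": "trnP-TGG", "g": "trnE-TTC", "h": "trnH-GTG",
    "i": "trnN-TTT", "j": "trnS-TGA", "k": "trnY-GTA", "l": "trnD-GTC",
    "m": "trnM-CAT", "n": "trnV-TAC", "o": "trnG-TCC", "p": "trnF-GAA",
    "q": "trnW-TCA", "r": "trnR-TCG", "s": "trnL-TAA", "t": "trnQ-TTG",
    "u": "trnN-GTT", "v": "trnT-TGT", "w": "trnA-TGC", "x": "trnS-TCT",
    "1": "COX1", "2": "ND1", "3": "ND2", "4": "COX2", "5": "CYTB",
    "6": "ND4", "7": "ND3", "8": "ND5", "9": "ND4L", "10": "ND6",
    "11": "COX3", "A": "rrnL", "B": "ATP8", "C": "ATP6", "D": "rrnS",
}

#: The eight gene clusters shared by the two genomes, in short codes.
SHARED_CLUSTER_NOTATION = (
    "1-a-2-3", "e-4", "A-D-6", "C-7-8", "10-i-n", "p-q-r-s",
    "t-u-v-c-w", "11-B",
)

#: Cluster reported as mutually reversed between the two genomes.
REVERSED_CLUSTER_NOTATION = "g-h"

#: Genes present in only one of the two genomes.
NONCOMMON_GENES = {
    RPHIL: ("trnY-ATA", "trnP-TGG", "trnS-TCT"),
    RVAR: ("trnP-AGG",),
}

#: Genes with two annotated copies.
DUPLICATED_GENES = {
    RPHIL: ("COX2", "trnM-CAT", "trnN-GTT", "trnV-TAC"),
    RVAR: ("trnC-GCA",),
}

#: Local gene-order region explained by tandem duplication-random loss:
#: k-m-m-l-n in R. philippinarum against k-l-m in R. variegatus.
TDRL_REGION = {RPHIL: ("k", "m", "m", "l", "n"), RVAR: ("k", "l", "m")}


def expand_short_codes(notation: str) -> tuple[str, ...]:
    """Expand a dash-separated short-code string to gene labels."""
    return tuple(SHORT_CODES[tok] for tok in notation.split("-"))


def codon_total_discrepancy(species: str) -> dict[str, int]:
    """Report the internal inconsistency between the printed codon total
    and the codon count implied by the printed PCG lengths.

    The printed codon-usage total and the printed per-gene lengths are
    each self-consistent but disagree with one another; both numbers are
    reported side by side, unresolved.
    """
    printed = sum(CODON_COUNTS[species].values())
    from_lengths = sum(
        length // 3 - 1 for (_, length, _, _, _) in PCG_PROFILES[species]
    )  # minus the stop codon of each gene
    return {
        "printed_codon_total": printed,
        "codons_from_gene_lengths": from_lengths,
        "difference": printed - from_lengths,
    }
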