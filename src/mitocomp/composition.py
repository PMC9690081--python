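"""Base composition, GC/AT content, strand skews and per-feature-class
genome proportions.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C) measure strand
asymmetry; percentages are computed over counted A/C/G/T with N excluded
from the denominator (the N count is reported separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genomes import CONTROL, PCG, RRNA, TRNA, AnnotatedGenome

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionSummary:
    """Composition of one sequence (fractions; percentages via pct_*)."""

    a: float
    c: float
    g: float
    t: float
    gc: float
    at: float
    at_skew: float
    gc_skew: float
    size_bp: int
    n_count: int = 0
    undefined_at_skew: bool = False
    undefined_gc_skew: bool = False

    def pct(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "A%": round_half_up(100 * self.a, ndigits),
            "C%": round_half_up(100 * self.c, ndigits),
            "G%": round_half_up(100 * self.g, ndigits),
            "T%": round_half_up(100 * self.t, ndigits),
            "GC%": round_half_up(100 * self.gc, ndigits),
            "AT%": round_half_up(100 * self.at, ndigits),
        }


def base_composition(seq: str) -> CompositionSummary:
    """Composition summary of a nucleotide sequence.

    A zero denominator makes a skew undefined; it is reported as 0.0 with
    the corresponding ``undefined_*_skew`` flag set.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_count = seq.count("N")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    a, c, g, t = (counts[b] / total for b in "ACGT")
    at_sum, gc_sum = counts["A"] + counts["T"], counts["G"] + counts["C"]
    und_at, und_gc = at_sum == 0, gc_sum == 0
    return CompositionSummary(
        a=a, c=c, g=g, t=t, gc=g + c, at=a + t,
        at_skew=0.0 if und_at else (counts["A"] - counts["T"]) / at_sum,
        gc_skew=0.0 if und_gc else (counts["G"] - counts["C"]) / gc_sum,
        size_bp=len(seq), n_count=n_count,
        undefined_at_skew=und_at, undefined_gc_skew=und_gc,
    )


#: Row order of the per-class summary table.
CLASS_ROWS = ("whole genome", PCG, TRNA, RRNA, CONTROL)


def class_sequence(genome: AnnotatedGenome, feature_class: str) -> str:
    """Concatenation of a class's feature slices, strand-oriented.

    Overlapping features contribute independently, so duplicated genes
    inflate the class size above the unique genomic span — matching how
    published per-class tables count them.
    """
    return "".join(
        genome.slice(f, oriented=True)
        for f in genome.features_of_class(feature_class)
    )


def feature_class_summary(genome: AnnotatedGenome) -> pd.DataFrame:
    """Per-class composition and proportion-of-genome table.

    Rows: whole genome, then PCG/tRNA/rRNA/control-region classes that
    are present (absent classes are omitted with a log note).
    """
    rows = []
    for cls in CLASS_ROWS:
        if cls == "whole genome":
            seq = genome.sequence
        else:
            seq = class_sequence(genome, cls)
            if not seq:
                log.info("%s: no %s features; row omitted", genome.id, cls)
                continue
        comp = base_composition(seq)
        row = {"class": cls, **comp.pct(1)}
        row["Size (bp)"] = comp.size_bp
        row["Proportion (%)"] = round_half_up(100 * comp.size_bp / len(genome), 2)
        row["AT skew"] = round_half_up(comp.at_skew, 3)
        row["GC skew"] = round_half_up(comp.gc_skew, 3)
        rows.append(row)
    return pd.DataFrame(rows)
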