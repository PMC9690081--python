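"""Codon counting, relative synonymous codon usage (RSCU), start/stop
profiling, amino-acid usage ranking and degenerate-site composition.

RSCU of a codon c in a synonymous family F of size k is

    RSCU(c) = count(c) / mean count over F = k * count(c) / sum_F count

so RSCU = 1 means no bias within the family.  Which codons form a family
is set by the :class:`~mitocomp.codes.RscuPartition` — see
:func:`mitocomp.codes.rscu_partition` for the two supported dialects.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .codes import CODONS, GeneticCode, RscuPartition, dna, genetic_code, rna
from .composition import round_half_up
from .genomes import AnnotatedGenome, CdsRecord, extract_cds

log = logging.getLogger(__name__)


def count_codons(cds_list, code: GeneticCode | int = 5,
                 exclude_stop_counts: bool = True) -> Counter:
    """Count codons over a list of CDS.

    Accepts :class:`CdsRecord` objects or plain sequences.  With
    ``exclude_stop_counts`` (the default, matching published totals),
    codons that are excluded under the code's RSCU partition — the true
    stop codons — are dropped from the counts.  Codons containing N are
    skipped and tallied under the key ``"N-containing"`` of the returned
    counter's ``ambiguous`` attribute companion (returned counts hold
    unambiguous codons only).
    """
    if isinstance(code, int):
        code = genetic_code(code)
    seqs = [c.sequence if isinstance(c, CdsRecord) else str(c) for c in cds_list]
    if not seqs:
        raise ValueError("empty CDS list")
    counts: Counter = Counter()
    skipped_n = 0
    for seq in seqs:
        seq = dna(seq.upper())
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                skipped_n += 1
                continue
            counts[codon] += 1
    if skipped_n:
        log.info("skipped %d codons containing N", skipped_n)
    if exclude_stop_counts:
        for codon in code.partition.excluded:
            counts.pop(codon, None)
    counts.n_skipped = skipped_n  # type: ignore[attr-defined]
    return counts


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts and RSCU values for one genome's PCG set."""

    genome_id: str
    partition_id: str
    counts: dict[str, int]
    rscu: dict[str, float]
    total_codons: int
    zero_family_codons: tuple[str, ...] = ()
    aa_labels: dict[str, str] = field(default_factory=dict)

    def rscu_2dp(self, codon: str) -> float:
        return round_half_up(self.rscu[dna(codon)], 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": rna(c),
                "aa": self.aa_labels.get(c, ""),
                "count": self.counts.get(c, 0),
                "RSCU": round_half_up(self.rscu[c], 2),
            }
            for c in CODONS
            if c not in _excluded_codons(self.partition_id)
        ]
        return pd.DataFrame(rows)


def _excluded_codons(partition_id: str):
    from .codes import rscu_partition

    try:
        return rscu_partition(partition_id).excluded
    except KeyError:
        return frozenset()


def rscu(counts, partition: RscuPartition | GeneticCode | None = None,
         genome_id: str = "", label_code: GeneticCode | int = 5) -> CodonUsageTable:
    """Compute RSCU values from codon counts under a family partition.

    A family whose total count is zero has undefined RSCU; its codons
    are reported as 0 and listed in ``zero_family_codons``.  Amino-acid
    display labels come from ``label_code`` (translation semantics),
    which may differ from the partition (family semantics).
    """
    if partition is None:
        partition = genetic_code(5).partition
    if isinstance(partition, GeneticCode):
        partition = partition.partition
    if isinstance(label_code, int):
        label_code = genetic_code(label_code)
    counts = {dna(c): n for c, n in dict(counts).items()}
    unknown = set(counts) - set(CODONS)
    if unknown:
        raise KeyError(f"codons absent from partition: {sorted(unknown)}")

    fam_totals: dict[str, int] = {}
    fam_sizes: dict[str, int] = {}
    for c in CODONS:
        lab = partition.codon_family[c]
        fam_sizes[lab] = fam_sizes.get(lab, 0) + 1
        fam_totals[lab] = fam_totals.get(lab, 0) + counts.get(c, 0)

    values: dict[str, float] = {}
    zero_fams: list[str] = []
    for c in CODONS:
        lab = partition.codon_family[c]
        if fam_totals[lab] == 0:
            values[c] = 0.0
            zero_fams.append(c)
        else:
            values[c] = fam_sizes[lab] * counts.get(c, 0) / fam_totals[lab]
    if zero_fams:
        log.info("RSCU undefined (zero family total) for %s", zero_fams)

    countable = [c for c in CODONS if c not in partition.excluded]
    total = sum(counts.get(c, 0) for c in countable)
    return CodonUsageTable(
        genome_id=genome_id,
        partition_id=partition.id,
        counts={c: counts.get(c, 0) for c in CODONS},
        rscu=values,
        total_codons=total,
        zero_family_codons=tuple(zero_fams),
        aa_labels={c: label_code.aa(c) for c in CODONS},
    )


def codon_usage_of_genome(genome: AnnotatedGenome,
                          code: GeneticCode | int = 5) -> CodonUsageTable:
    """Count codons over all PCGs of a genome and compute RSCU."""
    if isinstance(code, int):
        code = genetic_code(code)
    counts = count_codons(extract_cds(genome, code), code)
    return rscu(counts, code.partition, genome_id=genome.id, label_code=code)


def start_stop_table(genome: AnnotatedGenome,
                     code: GeneticCode | int = 5) -> pd.DataFrame:
    """Per-PCG table of length, literal first/last codon and direction.

    Starts not in the code's start-codon set are flagged non-canonical.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    rows = []
    for cds in extract_cds(genome, code):
        n = len(cds.sequence) - len(cds.sequence) % 3
        rows.append({
            "gene": cds.name,
            "copy": cds.copy_index,
            "length_bp": len(cds.sequence),
            "start_codon": cds.sequence[:3],
            "stop_codon": cds.sequence[n - 3:n],
            "direction": cds.strand,
            "canonical_start": cds.sequence[:3] in code.start_codons,
        })
    return pd.DataFrame(rows)


def aa_usage_ranking(counts, code: GeneticCode | int = 5) -> pd.DataFrame:
    """Total usage per amino acid, descending; ties broken alphabetically.

    Amino acids are grouped by the code's RSCU partition families, with
    display labels from the translation table.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    part = code.partition
    totals: dict[str, int] = {}
    for c, n in dict(counts).items():
        c = dna(c)
        if c in part.excluded:
            continue
        lab = part.codon_family[c]
        totals[lab] = totals.get(lab, 0) + n
    rows = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["amino_acid", "count"])


@dataclass(frozen=True)
class DegeneracyComposition:
    """Third-position base counts stratified by degeneracy class."""

    counts: dict[int, dict[str, int]]     # degeneracy d -> base -> count
    n_codons: dict[int, int]

    def at_fraction(self, d: int) -> float:
        row = self.counts.get(d, {})
        total = sum(row.values())
        if total == 0:
            raise ValueError(f"no codons in degeneracy class {d}")
        return (row.get("A", 0) + row.get("T", 0)) / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in sorted(self.counts):
            row = {"degeneracy": d, **{b: self.counts[d].get(b, 0) for b in "ACGT"}}
            row["AT_fraction"] = round_half_up(self.at_fraction(d), 3)
            rows.append(row)
        return pd.DataFrame(rows)


def degenerate_site_composition(cds_list, code: GeneticCode | int = 5
                                ) -> DegeneracyComposition:
    """Composition of third codon positions stratified by degeneracy.

    A codon's third-position degeneracy is the number of third-position
    states synonymous with it under the translation code (1-, 2-, 3- or
    4-fold).  Stop codons and codons containing N are skipped.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    counts: dict[int, dict[str, int]] = {}
    n_codons: dict[int, int] = {}
    seqs = [c.sequence if isinstance(c, CdsRecord) else str(c) for c in cds_list]
    for seq in seqs:
        seq = dna(seq.upper())
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if "N" in codon or code.is_stop(codon):
                continue
            d = code.third_position_degeneracy(codon)
            counts.setdefault(d, {})
            counts[d][codon[2]] = counts[d].get(codon[2], 0) + 1
            n_codons[d] = n_codons.get(d, 0) + 1
    return DegeneracyComposition(counts, n_codons)
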