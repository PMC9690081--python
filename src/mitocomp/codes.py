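"""Genetic-code tables and synonymous-family partitions.

Two code tables matter for mitochondrial work on molluscs: the standard
nuclear code (NCBI translation table 1) and the invertebrate mitochondrial
code (table 5), under which AUA encodes Met, UGA encodes Trp and AGA/AGG
encode Ser.  Codon-usage tables in the comparative-mitogenomics literature
are frequently computed with standard-code synonymous families even when
sequences are translated with table 5; both partitions are therefore
exposed here (see :func:`rscu_partition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
STOP = "*"

#: All 64 DNA codons in TCAG order.
CODONS = tuple("".join(c) for c in product(BASES, repeat=3))

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(b1: str, b2: str) -> bool:
    """True when the substitution b1->b2 is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    if b1 == b2:
        raise ValueError("identical bases are not a substitution")
    return (b1 in PURINES) == (b2 in PURINES)


def rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class RscuPartition:
    """A partition of the 64 codons into synonymous families.

    ``excluded`` lists codons whose *counts* are dropped before RSCU is
    computed (stop codons of the translation code in use); they still
    belong to a family so that family sizes are well defined.
    """

    id: str
    codon_family: dict[str, str]           # DNA codon -> family label
    excluded: frozenset[str]               # DNA codons dropped from counts

    def __post_init__(self) -> None:
        if set(self.codon_family) != set(CODONS):
            raise ValueError("partition must cover exactly the 64 codons")

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for c in CODONS:
            fams.setdefault(self.codon_family[c], []).append(c)
        return {k: tuple(v) for k, v in fams.items()}

    def family_of(self, codon: str) -> str:
        return self.codon_family[dna(codon)]

    def family_size(self, codon: str) -> int:
        lab = self.family_of(codon)
        return sum(1 for c in CODONS if self.codon_family[c] == lab)


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid map with start codons and an RSCU partition.

    ``codon_to_aa`` maps all 64 DNA codons; stops map to ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    partition: RscuPartition
    name: str = ""
    _neighbor_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            raise ValueError("code must map exactly the 64 codons")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c in CODONS if self.codon_to_aa[c] == STOP)

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[dna(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.aa(codon) == STOP

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.aa(c1) == self.aa(c2)

    def third_position_degeneracy(self, codon: str) -> int:
        """Number of third-position states (including the codon's own)
        encoding the same amino acid."""
        codon = dna(codon)
        aa = self.codon_to_aa[codon]
        return sum(
            1 for b in BASES if self.codon_to_aa[codon[:2] + b] == aa
        )

    def single_change_neighbors(self, codon: str):
        """All (position, base, neighbor_codon) single-nucleotide changes."""
        codon = dna(codon)
        cached = self._neighbor_cache.get(codon)
        if cached is None:
            out = []
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    out.append((pos, b, codon[:pos] + b + codon[pos + 1:]))
            cached = tuple(out)
            self._neighbor_cache[codon] = cached
        return cached


def _table_map(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = {c: tab.forward_table.get(c, STOP) for c in CODONS}
    return mapping, frozenset(tab.start_codons)


def _partition_from_map(pid: str, mapping: dict[str, str],
                        excluded: frozenset[str]) -> RscuPartition:
    return RscuPartition(pid, {c: mapping[c] for c in CODONS}, excluded)


@lru_cache(maxsize=None)
def rscu_partition(partition_id: str) -> RscuPartition:
    """Look up a named RSCU partition.

    ``table5-mito``
        Synonymous families follow the invertebrate mitochondrial code
        (AUA with Met, AGA/AGG with Ser, UGA with Trp); the UAA/UAG stop
        family is excluded from counting.  This is the biologically
        consistent choice for mitochondrial protein genes.
    ``table8-standard``
        Families follow the *standard* code (AUA with Ile in a 3-codon
        family, AGA/AGG with the 6-codon Arg family, UCN+AGY a 6-codon
        Ser family, UGA in the 3-codon stop family) while counts for the
        true mitochondrial stops UAA/UAG are excluded.  This dialect is
        what several published mollusc codon-usage tables actually print
        (the tell-tale signatures: RSCU(AUU) computed with family size 3,
        RSCU(AGA) with family size 6 and RSCU(UGA) = 3 exactly), so it is
        the default for reproducing them.
    """
    std_map, _ = _table_map(1)
    mito_map, _ = _table_map(5)
    mito_stops = frozenset(c for c in CODONS if mito_map[c] == STOP)  # TAA,TAG
    if partition_id == "table5-mito":
        return _partition_from_map(partition_id, mito_map, mito_stops)
    if partition_id == "table8-standard":
        return _partition_from_map(partition_id, std_map, mito_stops)
    raise KeyError(f"unknown RSCU partition {partition_id!r}")


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 5, partition_id: str | None = None) -> GeneticCode:
    """Build a :class:`GeneticCode` for NCBI table 1 or 5.

    The default partition is ``table8-standard`` for table 5 (the dialect
    used by the published tables this package reproduces) and the code's
    own families for table 1.
    """
    if table_id not in (1, 5):
        raise KeyError("supported translation tables: 1 (standard), 5 (invertebrate mito)")
    mapping, starts = _table_map(table_id)
    if partition_id is None:
        partition_id = "table8-standard" if table_id == 5 else "table1-standard"
    if partition_id == "table1-standard":
        stops = frozenset(c for c in CODONS if mapping[c] == STOP)
        part = _partition_from_map(partition_id, mapping, stops)
    else:
        part = rscu_partition(partition_id)
    names = {1: "standard", 5: "invertebrate mitochondrial"}
    return GeneticCode(table_id, mapping, starts, part, names[table_id])
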