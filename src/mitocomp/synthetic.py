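"""Seeded generators: annotated genome pairs, gene orders with known
rearrangement truth, and codon sequences evolved under a GY94-style
codon substitution model with specified omega (dN/dS), kappa (ts/tv) and
divergence.

Every generator takes an explicit integer seed and uses its own
`random.Random` instance (integer-state Mersenne Twister), so outputs
are bit-identical across platforms and no global random state is
touched.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .codes import CODONS, GeneticCode, dna, genetic_code, is_transition
from .gene_order import GeneOrder, replay_tdrl
from .genomes import (CONTROL, PCG, RRNA, TRNA, AnnotatedGenome, GeneFeature,
                      assign_copy_indices, reverse_complement)
from . import published

#: Canonical bilaterian mitochondrial gene inventory: 13 PCGs, 22 tRNAs,
#: 2 rRNAs and the control region.
CANONICAL_TRNAS = (
    "trnA-TGC", "trnR-TCG", "trnN-GTT", "trnD-GTC", "trnC-GCA", "trnQ-TTG",
    "trnE-TTC", "trnG-TCC", "trnH-GTG", "trnI-GAT", "trnL-TAA", "trnL-TAG",
    "trnK-CTT", "trnM-CAT", "trnF-GAA", "trnP-TGG", "trnS-TGA", "trnS-TCT",
    "trnT-TGT", "trnW-TCA", "trnY-GTA", "trnV-TAC",
)
CANONICAL_PCGS = (
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)
CANONICAL_INVENTORY = CANONICAL_PCGS + CANONICAL_TRNAS + ("rrnL", "rrnS", "D-loop")


def make_gene_order(n_genes: int = 37, seed: int = 0, id: str = "synthetic",
                    circular: bool = False) -> GeneOrder:
    """A random gene order sampled from the canonical inventory."""
    if not (1 <= n_genes <= len(CANONICAL_INVENTORY)):
        raise ValueError(f"n_genes must be in [1, {len(CANONICAL_INVENTORY)}]")
    rng = random.Random(seed)
    labels = list(CANONICAL_INVENTORY)
    rng.shuffle(labels)
    return GeneOrder(id, tuple((l, "+") for l in labels[:n_genes]), circular)


# ---------------------------------------------------------------------------
# rearrangement scripts

@dataclass(frozen=True)
class Reversal:
    start: int
    length: int


@dataclass(frozen=True)
class TDRL:
    start: int
    length: int
    retention: tuple[str, ...]  # per position: first|second|both


@dataclass(frozen=True)
class Delete:
    label: str


@dataclass(frozen=True)
class Insert:
    label: str
    position: int


@dataclass(frozen=True)
class Duplicate:
    label: str   # tandem duplication of a single gene


@dataclass(frozen=True)
class RearrangementScript:
    operations: tuple = ()
    seed: int = 0


def apply_rearrangements(order: GeneOrder, script: RearrangementScript):
    """Apply operations in sequence; returns (new order, truth records).

    Each truth record is sufficient to replay the operation.
    """
    items = list(order.items)
    truth = []
    for op in script.operations:
        if isinstance(op, Reversal):
            if not (0 <= op.start and op.start + op.length <= len(items)):
                raise ValueError(f"reversal block out of range: {op}")
            block = items[op.start:op.start + op.length]
            items[op.start:op.start + op.length] = [
                (l, "-" if s == "+" else "+") for l, s in reversed(block)]
            truth.append({"op": "reversal", "start": op.start,
                          "length": op.length,
                          "labels": tuple(l for l, _ in block)})
        elif isinstance(op, TDRL):
            labels = tuple(l for l, _ in items)
            new_labels = replay_tdrl(labels, op.start, op.length, op.retention)
            # rebuild strand list: duplicated block keeps source strands
            block = items[op.start:op.start + op.length]
            copy1 = [it for it, r in zip(block, op.retention) if r in ("first", "both")]
            copy2 = [it for it, r in zip(block, op.retention) if r in ("second", "both")]
            items = items[:op.start] + copy1 + copy2 + items[op.start + op.length:]
            assert tuple(l for l, _ in items) == new_labels
            truth.append({"op": "tdrl", "start": op.start, "length": op.length,
                          "retention": op.retention,
                          "labels": tuple(l for l, _ in block)})
        elif isinstance(op, Delete):
            idx = next((i for i, (l, _) in enumerate(items) if l == op.label), None)
            if idx is None:
                raise ValueError(f"cannot delete absent label {op.label}")
            items.pop(idx)
            truth.append({"op": "delete", "label": op.label, "position": idx})
        elif isinstance(op, Insert):
            if not (0 <= op.position <= len(items)):
                raise ValueError(f"insert position out of range: {op}")
            items.insert(op.position, (op.label, "+"))
            truth.append({"op": "insert", "label": op.label,
                          "position": op.position})
        elif isinstance(op, Duplicate):
            idx = next((i for i, (l, _) in enumerate(items) if l == op.label), None)
            if idx is None:
                raise ValueError(f"cannot duplicate absent label {op.label}")
            items.insert(idx + 1, items[idx])
            truth.append({"op": "duplicate", "label": op.label, "position": idx})
        else:
            raise TypeError(f"unknown operation {op!r}")
        if not items:
            raise ValueError("script removed every gene")
    return GeneOrder(order.id + "_rearranged", tuple(items), order.circular), truth


# ---------------------------------------------------------------------------
# codon-level simulation

@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the codon substitution model.

    omega is the nonsynonymous/synonymous rate ratio, kappa the
    transition/transversion rate ratio, t the expected number of
    substitutions per codon separating the pair (the two descendants sit
    at t/2 each from the ancestor).  codon_freqs maps DNA codons to
    equilibrium frequencies (stops must be 0); None means F3x4 fitted to
    the published Ruditapes philippinarum codon counts.
    """

    omega: float
    kappa: float
    t: float
    codon_freqs: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def f3x4_from_counts(counts, code: GeneticCode | int = 5) -> dict[str, float]:
    """F3x4 codon frequencies fitted to a codon-count table."""
    if isinstance(code, int):
        code = genetic_code(code)
    pos = [dict.fromkeys("TCAG", 0.0) for _ in range(3)]
    for codon, n in dict(counts).items():
        codon = dna(codon)
        for i, b in enumerate(codon):
            pos[i][b] += n
    for p in pos:
        tot = sum(p.values())
        for b in p:
            p[b] /= tot
    pi = {c: pos[0][c[0]] * pos[1][c[1]] * pos[2][c[2]]
          for c in CODONS if not code.is_stop(c)}
    tot = sum(pi.values())
    return {c: v / tot for c, v in pi.items()}


def default_codon_frequencies(code: GeneticCode | int = 5) -> dict[str, float]:
    return f3x4_from_counts(published.CODON_COUNTS[published.RPHIL], code)


def uniform_codon_frequencies(code: GeneticCode | int = 5) -> dict[str, float]:
    if isinstance(code, int):
        code = genetic_code(code)
    sense = [c for c in CODONS if not code.is_stop(c)]
    return {c: 1.0 / len(sense) for c in sense}


class _CodonModel:
    """GY94-style rate structure: q_ij = pi_j * kappa^[ts] * omega^[nonsyn]
    for single-position changes, 0 otherwise, scaled to one expected
    substitution per codon per unit t at equilibrium."""

    def __init__(self, params: EvolutionParams, code: GeneticCode):
        self.code = code
        self.pi = dict(params.codon_freqs or default_codon_frequencies(code))
        bad = [c for c in self.pi if code.is_stop(c) and self.pi[c] > 0]
        if bad:
            raise ValueError(f"stop codons must have zero frequency: {bad}")
        self.neighbors: dict[str, list[tuple[str, float, bool]]] = {}
        mean_rate = 0.0
        for c in CODONS:
            if code.is_stop(c):
                continue
            lst = []
            for pos, b, nbr in code.single_change_neighbors(c):
                if code.is_stop(nbr) or self.pi.get(nbr, 0.0) == 0.0:
                    continue
                syn = code.is_synonymous(c, nbr)
                r = self.pi[nbr]
                if is_transition(c[pos], b):
                    r *= params.kappa
                if not syn:
                    r *= params.omega
                lst.append((nbr, r, syn))
            self.neighbors[c] = lst
            mean_rate += self.pi.get(c, 0.0) * sum(r for _, r, _ in lst)
        if mean_rate <= 0:
            raise ValueError("degenerate model: zero mean substitution rate")
        self.scale = 1.0 / mean_rate

    def total_rate(self, codon: str) -> float:
        return self.scale * sum(r for _, r, _ in self.neighbors[codon])

    def synonymous_event_rate(self) -> float:
        """Expected synonymous substitutions per codon per unit t at
        equilibrium."""
        return self.scale * sum(
            self.pi.get(c, 0.0) * sum(r for _, r, syn in self.neighbors[c] if syn)
            for c in self.neighbors)

    def synonymous_sites_per_codon(self) -> float:
        """Equilibrium-average synonymous sites per codon, counted with
        the same mutational-opportunity weighting the estimators use
        (frequency- and kappa-weighted, omega excluded)."""
        total = 0.0
        for c in self.neighbors:
            syn_w = tot_w = 0.0
            for pos, b, nbr in self.code.single_change_neighbors(c):
                if self.code.is_stop(nbr) or self.pi.get(nbr, 0.0) == 0.0:
                    continue
                w = self.pi[nbr]
                tot_w += w
                if self.code.is_synonymous(c, nbr):
                    syn_w += w
            total += self.pi.get(c, 0.0) * (3.0 * syn_w / tot_w if tot_w else 0.0)
        return total

    def evolve_codon(self, codon: str, t: float, rng: random.Random):
        """Exact stochastic simulation of one codon along a branch."""
        events = []
        cur = codon
        remaining = t
        while True:
            rate = self.total_rate(cur)
            if rate <= 0:
                break
            wait = rng.expovariate(rate)
            if wait > remaining:
                break
            remaining -= wait
            lst = self.neighbors[cur]
            weights = [r for _, r, _ in lst]
            x = rng.random() * sum(weights)
            acc = 0.0
            for (nbr, r, syn) in lst:
                acc += r
                if x <= acc:
                    events.append(syn)
                    cur = nbr
                    break
        return cur, events


def evolve_codon_pair(ancestor_cds: str, params: EvolutionParams,
                      code: GeneticCode | int = 5):
    """Evolve two independent descendants of a CDS at divergence t.

    Returns (seq1, seq2, truth) where truth records the exact number of
    synonymous and nonsynonymous substitution events on each branch.
    Stop codons in the ancestor (e.g. the terminator) are left fixed.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor CDS length must be a multiple of 3")
    model = _CodonModel(params, code)
    rng = random.Random(params.seed)
    half = params.t / 2.0
    seqs = {1: [], 2: []}
    truth = {"syn_events": 0, "nonsyn_events": 0,
             "branch1": {"syn": 0, "nonsyn": 0},
             "branch2": {"syn": 0, "nonsyn": 0}}
    anc = dna(ancestor_cds.upper())
    for i in range(0, len(anc), 3):
        codon = anc[i:i + 3]
        if code.is_stop(codon) or "N" in codon or codon not in model.neighbors:
            seqs[1].append(codon)
            seqs[2].append(codon)
            continue
        for branch in (1, 2):
            desc, events = model.evolve_codon(codon, half, rng)
            seqs[branch].append(desc)
            for syn in events:
                key = "syn" if syn else "nonsyn"
                truth[f"branch{branch}"][key] += 1
                truth[f"{key}_events"] += 1
    truth["total_events"] = truth["syn_events"] + truth["nonsyn_events"]
    return "".join(seqs[1]), "".join(seqs[2]), truth


def divergence_for_ks(params: EvolutionParams, target_ks: float,
                      code: GeneticCode | int = 5) -> float:
    """The divergence t (expected substitutions per codon) at which the
    model's expected synonymous divergence is approximately target_ks
    synonymous substitutions per synonymous site."""
    if isinstance(code, int):
        code = genetic_code(code)
    model = _CodonModel(params, code)
    rs = model.synonymous_event_rate()
    sc = model.synonymous_sites_per_codon()
    if rs <= 0:
        raise ValueError("model has no synonymous substitutions")
    return target_ks * sc / rs


def sample_cds_from_rscu(profile, n_codons: int, code: GeneticCode | int = 5,
                         seed: int = 0) -> str:
    """Sample a CDS whose internal codons follow a codon-count profile.

    Codons are drawn with probability proportional to their profile
    count (amino-acid usage x within-family RSCU combined); the CDS
    starts with ATG and ends with TAA, and contains no internal stop.
    n_codons counts all codons including start and stop.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    if n_codons < 3:
        raise ValueError("need at least start + one codon + stop")
    weights = {dna(c): float(n) for c, n in dict(profile).items()
               if n > 0 and not code.is_stop(dna(c))}
    if not weights:
        raise ValueError("profile has no usable codons")
    rng = random.Random(seed)
    codons = list(weights)
    w = [weights[c] for c in codons]
    body = rng.choices(codons, weights=w, k=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


# ---------------------------------------------------------------------------
# whole-genome pair generation

@dataclass(frozen=True)
class GenomePairConfig:
    n_trnas: int = 22
    pcg_codons: int = 120          # codons per synthetic PCG incl. start/stop
    trna_bp: int = 66
    rrna_bp: tuple[int, int] = (1200, 850)
    dloop_bp: int = 900
    omega: float = 0.2
    kappa: float = 2.0
    t: float = 0.4
    script: RearrangementScript = field(default_factory=RearrangementScript)
    circular: bool = True


def _random_seq(rng: random.Random, length: int, at_bias: float = 0.66) -> str:
    at = at_bias / 2
    gc = (1 - at_bias) / 2
    return "".join(rng.choices("ATGC", weights=[at, at, gc, gc], k=length))


def make_genome_pair(config: GenomePairConfig, seed: int = 0,
                     code: GeneticCode | int = 5):
    """Two annotated genomes whose gene orders differ by a known script
    and whose shared PCGs diverged under the codon model.

    Returns (genome_a, genome_b, truth) where truth carries the script
    records, per-gene substitution counts and the model parameters.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    rng = random.Random(seed)
    order_a = make_gene_order(
        n_genes=13 + config.n_trnas + 3, seed=rng.randrange(2**31),
        id="synthA", circular=config.circular)
    order_b, script_truth = apply_rearrangements(order_a, config.script)
    order_b = GeneOrder("synthB", order_b.items, order_b.circular)

    profile = published.CODON_COUNTS[published.RPHIL]
    gene_seqs_a: dict[str, str] = {}
    gene_seqs_b: dict[str, str] = {}
    gene_truth: dict[str, dict] = {}
    for label in sorted({l for l, _ in order_a.items} | {l for l, _ in order_b.items}):
        if label in CANONICAL_PCGS:
            anc = sample_cds_from_rscu(profile, config.pcg_codons, code,
                                       seed=rng.randrange(2**31))
            params = EvolutionParams(config.omega, config.kappa, config.t,
                                     seed=rng.randrange(2**31))
            s1, s2, t = evolve_codon_pair(anc, params, code)
            gene_seqs_a[label], gene_seqs_b[label] = s1, s2
            gene_truth[label] = t
        elif label.startswith("trn"):
            gene_seqs_a[label] = gene_seqs_b[label] = _random_seq(rng, config.trna_bp)
        elif label == "rrnL":
            gene_seqs_a[label] = gene_seqs_b[label] = _random_seq(rng, config.rrna_bp[0])
        elif label == "rrnS":
            gene_seqs_a[label] = gene_seqs_b[label] = _random_seq(rng, config.rrna_bp[1])
        else:  # control region
            gene_seqs_a[label] = gene_seqs_b[label] = _random_seq(rng, config.dloop_bp)

    def assemble(order: GeneOrder, seqs: dict[str, str], gid: str) -> AnnotatedGenome:
        parts = []
        feats = []
        pos = 0
        for label, strand in order.items:
            s = seqs[label]
            if strand == "-":
                s = reverse_complement(s)
            fclass = (PCG if label in CANONICAL_PCGS else
                      TRNA if label.startswith("trn") else
                      RRNA if label.startswith("rrn") else CONTROL)
            feats.append(GeneFeature(label, fclass, pos, pos + len(s), strand))
            parts.append(s)
            pos += len(s)
        return AnnotatedGenome(gid, "".join(parts), config.circular,
                               tuple(assign_copy_indices(feats)), "synthetic")

    genome_a = assemble(order_a, gene_seqs_a, "synthA")
    genome_b = assemble(order_b, gene_seqs_b, "synthB")
    truth = {
        "script": script_truth,
        "genes": gene_truth,
        "params": {"omega": config.omega, "kappa": config.kappa, "t": config.t},
        "order_a": order_a.labels, "order_b": order_b.labels,
    }
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# synthetic reconstruction of the published gene-order comparison

_RPHIL_CODES = (
    "D-loop 1 a b 2 3 g h e 4 4 A D 6 5 C 7 8 9 10 i n k m m l n "
    "p q r s j t u v c w u o 11 B f x"
).split()
_RVAR_CODES = (
    "1 a d 2 3 h g e 4 5 A D 6 o C 7 8 j 10 i n 9 k l m "
    "p q r s t u v c w c 11 B D-loop"
).split()


def ruditapes_like_order_pair() -> tuple[GeneOrder, GeneOrder]:
    """SYNTHETIC reconstruction of the two Ruditapes-like gene orders.

    The genuine orders of the deposited genomes are not printed anywhere
    in full; this pair is *constructed* to satisfy every published
    constraint simultaneously — the eight shared clusters (1-a-2-3, e-4,
    A-D-6, C-7-8, 10-i-n, p-q-r-s, t-u-v-c-w, 11-B) in consistent
    sequential order, the mutually reversed g-h cluster (modelled as a
    strand-flipping inversion), the k-m-m-l-n vs k-l-m TDRL region, the
    duplicated genes (COX2, trnM-CAT, trnN-GTT, trnV-TAC in one genome;
    trnC-GCA in the other) and the noncommon tRNAs.  It is a test bed
    for the gene-order operations, not the deposited annotation.
    """
    def expand(codes, flip: set[str], gid: str) -> GeneOrder:
        items = []
        for tok in codes:
            label = published.SHORT_CODES.get(tok, tok)
            items.append((label, "-" if tok in flip else "+"))
        return GeneOrder(gid, tuple(items), circular=False)

    rp = expand(_RPHIL_CODES, set(), "synthetic_R_philippinarum")
    rv = expand(_RVAR_CODES, {"g", "h"}, "synthetic_R_variegatus")
    return rp, rv
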