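"""Ka/Ks estimators: NG86 counting, YN00, Fisher validation."""

import math
import random
from itertools import permutations

import pytest
from scipy.stats import hypergeom

from mitocomp import published as pub
from mitocomp.alignment import CodonAlignment
from mitocomp.codes import CODONS, genetic_code, is_transition
from mitocomp.selection import (
    KaKsResult,
    fisher_kaks,
    kaks_ng86,
    kaks_yn00,
    pairwise_kaks_matrix,
)
from mitocomp.synthetic import (
    EvolutionParams,
    GenomePairConfig,
    divergence_for_ks,
    evolve_codon_pair,
    make_genome_pair,
    sample_cds_from_rscu,
)
from tests.conftest import codon_alignment_from


def simulated_caln(code, omega, kappa, t, n_codons, seed, freqs=None):
    anc = sample_cds_from_rscu(pub.CODON_COUNTS[pub.RPHIL], n_codons + 2,
                               code, seed=seed)
    params = EvolutionParams(omega, kappa, t, codon_freqs=freqs, seed=seed + 10_000)
    s1, s2, truth = evolve_codon_pair(anc, params, code)
    return codon_alignment_from(s1, s2, code), truth


# ---------------------------------------------------------------------------
# NG86

def test_identical_sequences_ng86(code5):
    caln = CodonAlignment("g", ("ATG", "AAA"), ("ATG", "AAA"), ("", ""))
    r = kaks_ng86(caln, code5)
    assert r.Sd == r.Nd == 0
    assert r.ka == 0 and r.ks == 0
    assert math.isnan(r.ratio)


def test_ng86_hand_worked_example(code5):
    """Third-position synonymous fractions and the single-pathway count
    enumerated by hand for a 3-codon pair with one synonymous change."""
    caln = CodonAlignment("g", ("TTT", "GGG", "CAT"), ("TTC", "GGG", "CAT"),
                          ("", ""))
    r = kaks_ng86(caln, code5)
    assert r.S == pytest.approx(5 / 3)
    assert r.N == pytest.approx(22 / 3)
    assert r.Sd == pytest.approx(1.0) and r.Nd == pytest.approx(0.0)
    assert r.ka == 0.0
    assert r.ks == pytest.approx(-0.75 * math.log(0.2))


def ng86_pair_oracle(x, y, code):
    """Independent pathway enumeration: average syn/nonsyn steps over
    all stop-free orderings of the differing positions."""
    diff = [i for i in range(3) if x[i] != y[i]]
    results = []
    for order in permutations(diff):
        cur, sd, nd, ok = x, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + y[pos] + cur[pos + 1:]
            if code.aa(nxt) == "*":
                ok = False
                break
            if code.aa(cur) == code.aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def test_ng86_differences_match_exhaustive_pathway_oracle(code5):
    """NG86 equals brute-force pathway enumeration on every ordered
    non-stop codon pair (64x64 exhaustive check)."""
    sense = [c for c in CODONS if not code5.is_stop(c)]
    anchor = ("ATG", "ATG")  # guarantees S > 0 denominator is irrelevant here
    for x in sense:
        for y in sense:
            if x == y:
                continue
            caln = CodonAlignment("g", (anchor[0], x), (anchor[1], y), ("", ""))
            r = kaks_ng86(caln, code5)
            oracle = ng86_pair_oracle(x, y, code5)
            if oracle is None:
                assert r.Sd == 0 and r.Nd == 0
                assert "blocked_pair_skipped" in r.flags
            else:
                assert r.Sd == pytest.approx(oracle[0], abs=1e-12)
                assert r.Nd == pytest.approx(oracle[1], abs=1e-12)


def test_ng86_sites_match_per_position_oracle(code5):
    """Per-codon synonymous sites recomputed independently position by
    position with stop mutations excluded."""
    rng = random.Random(8)
    sense = [c for c in CODONS if not code5.is_stop(c)]
    for codon in rng.sample(sense, 20):
        caln = CodonAlignment("g", (codon,), (codon,), ("", ""))
        r = kaks_ng86(caln, code5)
        s = 0.0
        for pos in range(3):
            changes = [codon[:pos] + b + codon[pos + 1:]
                       for b in "ACGT" if b != codon[pos]]
            non_stop = [c for c in changes if code5.aa(c) != "*"]
            syn = [c for c in non_stop if code5.aa(c) == code5.aa(codon)]
            if non_stop:
                s += len(syn) / len(non_stop)
        assert r.S == pytest.approx(s, abs=1e-12)


# ---------------------------------------------------------------------------
# shared invariants

@pytest.mark.parametrize("method", [kaks_ng86, kaks_yn00])
def test_sites_sum_to_three_per_codon(method, code5):
    for seed in range(3):
        caln, _ = simulated_caln(code5, 0.4, 2.0, 0.5, 200, seed)
        r = method(caln, code5)
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-6)
        assert r.Sd <= sum(c1 != c2 for c1, c2 in caln.pairs()) * 3 + 1e-9


@pytest.mark.parametrize("method", [kaks_ng86, kaks_yn00])
def test_symmetry_under_sequence_swap(method, code5):
    caln, _ = simulated_caln(code5, 0.3, 2.0, 0.6, 150, 42)
    fwd = method(caln, code5)
    rev = method(CodonAlignment(caln.gene, caln.codons2, caln.codons1,
                                ("", "")), code5)
    for attr in ("S", "N", "Sd", "Nd", "ka", "ks"):
        assert getattr(fwd, attr) == pytest.approx(getattr(rev, attr),
                                                   abs=1e-9)


def test_mean_ka_increases_with_omega(code5):
    """At fixed divergence, stronger omega leaves more nonsynonymous
    differences."""
    means = []
    for omega in (0.1, 0.5, 1.0):
        kas = []
        for seed in range(10):
            caln, _ = simulated_caln(code5, omega, 2.0, 0.5, 300,
                                     seed + int(100 * omega))
            kas.append(kaks_ng86(caln, code5).ka)
        means.append(sum(kas) / len(kas))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# YN00 specifics

def test_identical_sequences_yn00(code5):
    caln = CodonAlignment("g", ("ATG", "AAA", "CCT"), ("ATG", "AAA", "CCT"),
                          ("", ""))
    r = kaks_yn00(caln, code5)
    assert r.ka == 0.0 and r.ks == 0.0
    assert math.isnan(r.ratio)
    assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-6)


def test_yn00_kappa_recovery(code5):
    kappas = []
    for seed in range(10):
        caln, _ = simulated_caln(code5, 0.3, 4.0, 0.5, 500, seed)
        kappas.append(kaks_yn00(caln, code5).kappa)
    mean = sum(kappas) / len(kappas)
    assert 2.5 < mean < 6.0


def test_yn00_short_alignment_warns(code5, caplog):
    caln = CodonAlignment("tiny", ("ATG", "AAA"), ("ATG", "AAG"), ("", ""))
    with caplog.at_level("WARNING"):
        kaks_yn00(caln, code5)
    assert any("unreliable" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# Fisher exact validation

def fisher_enumeration_oracle(sd, s_rest, nd, n_rest) -> float:
    """Two-sided Fisher p by exhaustive enumeration over all tables with
    the observed margins."""
    row1, col1 = sd + s_rest, sd + nd
    total = sd + s_rest + nd + n_rest
    obs = hypergeom.pmf(sd, total, row1, col1)
    p = 0.0
    for k in range(max(0, col1 - (total - row1)), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, total, row1, col1)
        if pk <= obs * (1 + 1e-12):
            p += pk
    return min(p, 1.0)


def test_fisher_no_differences_gives_p_one(code5):
    r = KaKsResult("NG86", "g", 10, 8.0, 22.0, 0.0, 0.0, 0.0, 0.0)
    assert fisher_kaks(r) == pytest.approx(1.0)


@pytest.mark.parametrize("cells", [
    (2, 8, 1, 25),
    (5, 5, 5, 5),
    (0, 12, 7, 3),
    (10, 0, 0, 10),
    (3, 17, 9, 11),
])
def test_fisher_matches_enumeration(cells):
    sd, s_rest, nd, n_rest = cells
    r = KaKsResult("NG86", "g", 10, float(sd + s_rest), float(nd + n_rest),
                   float(sd), float(nd), 0.0, 0.0)
    assert fisher_kaks(r) == pytest.approx(
        fisher_enumeration_oracle(sd, s_rest, nd, n_rest), abs=1e-12)


def test_fisher_negative_cell_errors():
    r = KaKsResult("NG86", "g", 10, 4.0, 8.0, 6.0, 1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        fisher_kaks(r)


def test_fisher_detects_strong_purifying_selection(code5):
    """omega = 0.05 at 500 codons is called significant in >= 90% of
    replicates."""
    t = divergence_for_ks(EvolutionParams(0.05, 2.0, 1.0), 0.3)
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        caln, _ = simulated_caln(code5, 0.05, 2.0, t, 500, seed)
        p = fisher_kaks(kaks_ng86(caln, code5))
        hits += p < 0.05
    assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# pairwise matrix

def test_pairwise_matrix_genome_vs_itself(code5):
    genome, _, _ = make_genome_pair(GenomePairConfig(t=0.0), seed=2)
    df = pairwise_kaks_matrix(genome, [genome], method="NG86", code=code5)
    assert (df["Ka"] == 0).all() and (df["Ks"] == 0).all()
    assert df["KaKs"].isna().all()


def test_pairwise_matrix_row_count_contract(code5):
    a, b, _ = make_genome_pair(GenomePairConfig(t=0.2), seed=6)
    df = pairwise_kaks_matrix(a, [b], method="NG86", code=code5)
    assert len(df) == 13  # all canonical PCGs shared
    df13 = pairwise_kaks_matrix(a, [b, b, b], genes=list(df["gene"]),
                                method="NG86", code=code5)
    assert len(df13) == 39


def test_pairwise_matrix_missing_gene_row(code5):
    a, b, _ = make_genome_pair(GenomePairConfig(t=0.1), seed=6)
    df = pairwise_kaks_matrix(a, [b], genes=["COX1", "NOTAGENE"],
                              method="NG86", code=code5)
    row = df[df["gene"] == "NOTAGENE"].iloc[0]
    assert row["reason"] == "missing homolog"
    assert len(df) == 2


def test_pairwise_matrix_no_shared_genes_errors(code5):
    a, _, _ = make_genome_pair(GenomePairConfig(t=0.0), seed=2)
    with pytest.raises((ValueError, KeyError)):
        pairwise_kaks_matrix(a, [a], genes=[], method="NG86", code=code5)
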