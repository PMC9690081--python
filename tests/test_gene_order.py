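"""Gene-order comparison: clusters, noncommon genes, TDRL inference."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import published as pub
from mitocomp.gene_order import (
    GeneOrder,
    cluster_is_valid,
    find_duplicates,
    noncommon_genes,
    order_from_labels,
    parse_order,
    private_genes,
    replay_tdrl,
    reversed_clusters,
    shared_clusters,
    tdrl_ancestral_candidates,
    tdrl_candidates,
)
from mitocomp.synthetic import (
    TDRL,
    RearrangementScript,
    Reversal,
    apply_rearrangements,
    make_gene_order,
    ruditapes_like_order_pair,
)


def substring_oracle(match, a, b) -> bool:
    """Independent cluster validation: the labels occur contiguously in
    the shared-label projection of both orders, in the right direction."""
    shared = set(a.labels) & set(b.labels)
    pa = tuple(l for l in a.labels if l in shared)
    pb = tuple(l for l in b.labels if l in shared)
    lab = match.labels
    want_b = lab if match.orientation == "same" else tuple(reversed(lab))

    def occurs(run, seq, circular):
        s = seq + seq[:len(run) - 1] if circular else seq
        return any(s[i:i + len(run)] == run for i in range(len(seq)))

    return occurs(lab, pa, a.circular) and occurs(want_b, pb, b.circular)


def test_identical_orders_single_full_cluster():
    a = order_from_labels("ABCD", "a")
    b = order_from_labels("ABCD", "b")
    (c,) = shared_clusters(a, b)
    assert c.labels == ("A", "B", "C", "D")


def test_disjoint_orders_no_clusters():
    a = order_from_labels("AB", "a")
    b = order_from_labels("CD", "b")
    assert shared_clusters(a, b) == []


def test_circular_self_comparison_covers_everything():
    a = order_from_labels("ABCDE", "a", circular=True)
    rotated = GeneOrder("b", a.items[2:] + a.items[:2], circular=True)
    (c,) = shared_clusters(a, rotated)
    assert len(c.labels) == 5


def test_transparency_rule_skips_private_genes():
    a = order_from_labels(["X", "p1", "Y", "Z"], "a")
    b = order_from_labels(["X", "Y", "p2", "Z"], "b")
    (c,) = shared_clusters(a, b)
    assert c.labels == ("X", "Y", "Z")


def test_reversed_cluster_detected_with_strand_flip():
    a = GeneOrder("a", (("A", "+"), ("B", "+"), ("C", "+")))
    b = GeneOrder("b", (("C", "-"), ("B", "-"), ("A", "-")))
    (c,) = reversed_clusters(a, b)
    assert c.labels == ("A", "B", "C")
    assert reversed_clusters(a, a) == []


def test_reversed_cluster_without_strand_flip_needs_relaxation():
    a = order_from_labels("AB", "a")
    b = order_from_labels("BA", "b")
    assert reversed_clusters(a, b) == []          # same strands: rejected
    (c,) = reversed_clusters(a, b, require_strand_flip=False)
    assert c.labels == ("A", "B")


def test_every_reported_cluster_revalidates():
    rng = random.Random(0)
    for seed in range(20):
        a = make_gene_order(25, seed=seed, id="a")
        script = RearrangementScript((Reversal(rng.randrange(5, 12), 4),))
        b, _ = apply_rearrangements(a, script)
        for c in shared_clusters(a, b) + reversed_clusters(a, b):
            assert cluster_is_valid(c, a, b)
            assert substring_oracle(c, a, b)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.sampled_from("ABCDEFG"), min_size=1, max_size=12),
       st.lists(st.sampled_from("ABCDEFG"), min_size=1, max_size=12))
def test_noncommon_genes_matches_multiset_oracle(la, lb):
    a, b = order_from_labels(la, "a"), order_from_labels(lb, "b")
    only_a, only_b = noncommon_genes(a, b)
    ca, cb = Counter(la), Counter(lb)
    assert Counter(only_a) == ca - cb
    assert Counter(only_b) == cb - ca


def test_find_duplicates():
    assert find_duplicates(order_from_labels("ABA")) == {"A": 2}
    assert find_duplicates(order_from_labels("ABC")) == {}


def test_parse_and_shortcode_expansion():
    o = parse_order("1-a-2", short_codes=pub.SHORT_CODES)
    assert o.labels == ("COX1", "trnL-TAG", "ND1")
    o2 = parse_order("COX1:+\nND1:-\n")
    assert o2.items == (("COX1", "+"), ("ND1", "-"))


# ---------------------------------------------------------------------------
# synthetic reconstruction of the published comparison

@pytest.fixture(scope="module")
def ruditapes_pair():
    return ruditapes_like_order_pair()


def test_reconstruction_recovers_the_eight_published_clusters(ruditapes_pair):
    rp, rv = ruditapes_pair
    got = sorted(c.labels for c in shared_clusters(rp, rv))
    want = sorted(pub.expand_short_codes(s) for s in pub.SHARED_CLUSTER_NOTATION)
    assert got == want
    assert len(got) == 8


def test_reconstruction_reversed_cluster_is_g_h(ruditapes_pair):
    rp, rv = ruditapes_pair
    (c,) = reversed_clusters(rp, rv)
    assert c.labels == pub.expand_short_codes(pub.REVERSED_CLUSTER_NOTATION)


def test_reconstruction_noncommon_genes(ruditapes_pair):
    rp, rv = ruditapes_pair
    only_rp, only_rv = private_genes(rp, rv)
    assert set(only_rp) == set(pub.NONCOMMON_GENES[pub.RPHIL])
    assert set(only_rv) == set(pub.NONCOMMON_GENES[pub.RVAR])


def test_reconstruction_duplicates(ruditapes_pair):
    rp, rv = ruditapes_pair
    assert set(find_duplicates(rp)) == set(pub.DUPLICATED_GENES[pub.RPHIL])
    assert "COX2" in find_duplicates(rp)
    assert set(find_duplicates(rv)) == set(pub.DUPLICATED_GENES[pub.RVAR])


def test_reconstruction_tdrl_region_shares_one_ancestral_duplication():
    """The published k-m-m-l-n / k-l-m regions are explained by a single
    ancestral tandem duplication of trnM-trnD with different losses."""
    ra = order_from_labels(pub.expand_short_codes(
        "-".join(pub.TDRL_REGION[pub.RPHIL])), "rp")
    rb = order_from_labels(pub.expand_short_codes(
        "-".join(pub.TDRL_REGION[pub.RVAR])), "rv")
    cands = tdrl_ancestral_candidates(ra, rb)
    assert len(cands) >= 1
    anc = cands[0]
    assert anc.block == ("trnM-CAT", "trnD-GTC")
    # replay both descents: prefix + copy1 + copy2 (+ suffix) on shared set
    shared = set(ra.labels) & set(rb.labels)
    sa = tuple(l for l in ra.labels if l in shared)
    sb = tuple(l for l in rb.labels if l in shared)
    assert anc.ancestor[:1] + anc.split_a[0] + anc.split_a[1] == sa[:1] + sa[1:]
    assert sb == sb[:1] + anc.split_b[0] + anc.split_b[1]


# ---------------------------------------------------------------------------
# TDRL event search

def test_no_event_needed_for_equal_orders():
    a = order_from_labels("KLM", "a")
    assert tdrl_candidates(a, a) == []


def test_single_tdrl_found_and_replays():
    a = order_from_labels(["k", "l", "m"], "a")
    b = order_from_labels(["k", "m", "l"], "b")
    events = tdrl_candidates(a, b)
    assert events
    for e in events:
        assert replay_tdrl(e.source, e.block_start, len(e.block),
                           e.retention) == e.result
        assert e.result == ("k", "m", "l")


def test_unreachable_order_yields_no_direct_event_but_an_ancestor():
    """k-m-m-l-n cannot be one tandem-duplication-random-loss away from
    k-l-m-n (no single duplication leaves an l after the second m), but
    one ancestral duplication explains both."""
    a = order_from_labels(["k", "l", "m", "n"], "a")
    b = order_from_labels(["k", "m", "m", "l", "n"], "b")
    assert tdrl_candidates(a, b) == []
    cands = tdrl_ancestral_candidates(a, b)
    assert any(c.ancestor == ("k", "m", "l", "n") and c.block == ("m", "l")
               for c in cands)


def test_tdrl_retaining_both_copies():
    a = order_from_labels(["k", "l", "m"], "a")
    b = order_from_labels(["k", "l", "m", "l", "m"], "b")  # block dup, all kept
    events = tdrl_candidates(a, b)
    assert any(set(e.retention) == {"both"} for e in events)


def test_search_space_cap_raises():
    a = make_gene_order(30, seed=1, id="a")
    b, _ = apply_rearrangements(a, RearrangementScript(
        (TDRL(5, 4, ("first", "second", "first", "both")),)))
    with pytest.raises(RuntimeError, match="search space"):
        tdrl_candidates(a, b, max_block=6, max_replays=10)


def planted_tdrl_case(seed: int):
    """A random order with one planted TDRL that actually changes it
    (all-first / all-second retentions are identity events)."""
    rng = random.Random(seed)
    order = make_gene_order(20, seed=seed, id="a")
    while True:
        length = rng.randrange(2, 5)
        start = rng.randrange(0, len(order) - length)
        retention = tuple(rng.choice(["first", "second", "both"])
                          for _ in range(length))
        script = RearrangementScript((TDRL(start, length, retention),))
        rearranged, truth = apply_rearrangements(order, script)
        if rearranged.labels != order.labels:
            return order, rearranged, truth[0]


def test_planted_tdrl_recovered_sample():
    """Candidate search finds an event replaying to the observed order
    for every planted case (small sample here; the full 200-seed sweep
    runs with the acceptance suite)."""
    for seed in range(20):
        a, b, truth = planted_tdrl_case(seed)
        events = tdrl_candidates(a, b)
        assert events, f"no event recovered for seed {seed}"
        shared = set(a.labels) & set(b.labels)
        sb = tuple(l for l in b.labels if l in shared)
        for e in events:
            assert replay_tdrl(e.source, e.block_start, len(e.block),
                               e.retention) == sb


def test_planted_reversal_recovered_sample():
    for seed in range(20):
        rng = random.Random(seed)
        a = make_gene_order(30, seed=seed, id="a")
        length = rng.randrange(2, 7)
        start = rng.randrange(0, len(a) - length)
        b, truth = apply_rearrangements(
            a, RearrangementScript((Reversal(start, length),)))
        found = reversed_clusters(a, b)
        planted = truth[0]["labels"]
        assert any(c.labels == planted for c in found)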