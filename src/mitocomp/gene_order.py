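"""Gene-order comparison: shared and reversed clusters, noncommon genes,
duplicates, and tandem duplication-random loss (TDRL) inference.

A *gene cluster* here is a maximal run of genes that is contiguous and
identically ordered in both genomes, where genes private to one genome
are transparent — skipped when testing contiguity.  Published cluster
notation elides the other genome's interleaved private tRNAs, and
without the transparency rule those printed clusters are irrecoverable.

Under the TDRL model a contiguous block is duplicated in tandem and one
copy of each duplicated gene is subsequently lost (occasionally both
copies are retained, leaving a duplicate).  Because sister genomes both
descend from an unobserved ancestor, a rearrangement that is a single
TDRL away from the ancestor need not be a single TDRL away from the
sister; :func:`tdrl_candidates` searches direct single events, and
:func:`tdrl_ancestral_candidates` searches for one ancestral duplication
whose two independent random losses yield both observed orders.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import permutations, product

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneOrder:
    """Ordered gene labels (with strands) of one genome."""

    id: str
    items: tuple[tuple[str, str], ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("empty gene order")
        items = tuple((str(l), s) for l, s in self.items)
        for label, strand in items:
            if not label:
                raise ValueError("empty gene label")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r} for {label}")
        object.__setattr__(self, "items", items)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.items)

    def __len__(self) -> int:
        return len(self.items)


def order_from_labels(labels, id: str = "", circular: bool = False,
                      strand: str = "+") -> GeneOrder:
    return GeneOrder(id, tuple((l, strand) for l in labels), circular)


def parse_order(text: str, id: str = "", circular: bool = False,
                short_codes: dict[str, str] | None = None) -> GeneOrder:
    """Parse ``label[:strand]`` tokens from dash-separated or line-based
    text; optional short-code expansion (figure-legend style)."""
    tokens = [t for line in text.strip().splitlines()
              for t in line.strip().split("-" if "-" in line and "\n" not in text.strip() else None)
              if t]
    if len(tokens) <= 1 and "-" in text:
        tokens = [t for t in text.strip().split("-") if t]
    items = []
    for tok in tokens:
        label, _, strand = tok.partition(":")
        if short_codes and label in short_codes:
            label = short_codes[label]
        items.append((label, strand or "+"))
    return GeneOrder(id, tuple(items), circular)


def format_order(order: GeneOrder) -> str:
    return "-".join(l if s == "+" else f"{l}:-" for l, s in order.items)


@dataclass(frozen=True)
class ClusterMatch:
    """A maximal shared (or reversed) gene cluster."""

    labels: tuple[str, ...]
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]
    orientation: str  # "same" | "reversed"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "reversed"):
            raise ValueError("orientation must be 'same' or 'reversed'")


# ---------------------------------------------------------------------------
# projection + occurrence matching

def _project(order: GeneOrder, shared: set[str]):
    return [(l, s, i) for i, (l, s) in enumerate(order.items) if l in shared]


def _greedy_match(pa, pb):
    """k-th occurrence of each label in a matches the k-th in b."""
    occ_b: dict[str, list[int]] = {}
    for j, (label, _, _) in enumerate(pb):
        occ_b.setdefault(label, []).append(j)
    seen: dict[str, int] = {}
    ma: list[int | None] = []
    for label, _, _ in pa:
        k = seen.get(label, 0)
        seen[label] = k + 1
        js = occ_b.get(label, [])
        ma.append(js[k] if k < len(js) else None)
    return ma


def _maximal_chains(n: int, valid, linked, circular: bool):
    """Maximal runs of valid columns joined by links, optionally circular."""
    if n == 0:
        return []
    if circular and all(valid(i) for i in range(n)) and all(
            linked(i) for i in range(n)):
        return [list(range(n))]
    chains = []
    idx = range(n) if not circular else range(n)
    started = [False] * n

    def prev(i):
        return (i - 1) % n if circular else i - 1

    for i in idx:
        if not valid(i):
            continue
        p = prev(i)
        if 0 <= p < n and valid(p) and linked(p):
            continue  # not a chain start
        chain = [i]
        cur = i
        while True:
            if not linked(cur):
                break
            nxt = (cur + 1) % n if circular else cur + 1
            if not (0 <= nxt < n) or not valid(nxt) or nxt == i:
                break
            chain.append(nxt)
            cur = nxt
        if started[i]:
            continue
        started[i] = True
        chains.append(chain)
    return chains


def _clusters(a: GeneOrder, b: GeneOrder, min_len: int, reversed_: bool,
              require_strand_flip: bool = True):
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty order")
    shared = set(a.labels) & set(b.labels)
    pa, pb = _project(a, shared), _project(b, shared)
    ma = _greedy_match(pa, pb)
    n, m = len(pa), len(pb)
    circular = a.circular and b.circular

    def strands_ok(i):
        la, sa, _ = pa[i]
        _, sb, _ = pb[ma[i]]
        if not reversed_:
            return sa == sb
        return (sa != sb) if require_strand_flip else True

    def valid(i):
        return ma[i] is not None and strands_ok(i)

    def linked(i):
        if not valid(i):
            return False
        nxt = (i + 1) % n if circular else i + 1
        if not (0 <= nxt < n) or not valid(nxt):
            return False
        j = ma[i]
        step = -1 if reversed_ else 1
        jn = (j + step) % m if circular else j + step
        return 0 <= jn < m and ma[nxt] == jn

    out = []
    for chain in _maximal_chains(n, valid, linked, circular):
        if len(chain) < min_len:
            continue
        out.append(ClusterMatch(
            labels=tuple(pa[i][0] for i in chain),
            positions_a=tuple(pa[i][2] for i in chain),
            positions_b=tuple(pb[ma[i]][2] for i in chain),
            orientation="reversed" if reversed_ else "same",
        ))
    return out


def shared_clusters(a: GeneOrder, b: GeneOrder, min_len: int = 2):
    """All maximal same-order clusters (transparency rule applied;
    duplicates matched greedily left to right; circular orders compared
    with wrap-around adjacency)."""
    return _clusters(a, b, min_len, reversed_=False)


def reversed_clusters(a: GeneOrder, b: GeneOrder, min_len: int = 2,
                      require_strand_flip: bool = True):
    """Maximal clusters whose occurrence in b is the exact reverse of
    their occurrence in a; runs already reported as 'same' are excluded.

    With ``require_strand_flip`` (default) each column must also flip
    strand, the signature of an inversion; annotations that keep
    everything on the plus strand can set it to False to detect
    position-only reversals.
    """
    rev = _clusters(a, b, min_len, reversed_=True,
                    require_strand_flip=require_strand_flip)
    same_pos = {frozenset(c.positions_a) for c in _clusters(a, b, min_len, False)}
    return [c for c in rev if frozenset(c.positions_a) not in same_pos]


def cluster_is_valid(match: ClusterMatch, a: GeneOrder, b: GeneOrder) -> bool:
    """Re-validate a cluster by direct contiguity check under the
    transparency rule."""
    shared = set(a.labels) & set(b.labels)

    def contiguous(order, positions, labels):
        proj = [i for (_, _, i) in _project(order, shared)]
        idx = [proj.index(p) for p in positions]
        return (all(idx[k + 1] == idx[k] + 1 for k in range(len(idx) - 1))
                or (order.circular and all(
                    (idx[k + 1] - idx[k]) % len(proj) == 1
                    for k in range(len(idx) - 1))))

    lab_a = tuple(a.items[p][0] for p in match.positions_a)
    lab_b = tuple(b.items[p][0] for p in match.positions_b)
    if lab_a != match.labels or lab_b != match.labels:
        return False  # column i matches the same label in both orders
    pb = match.positions_b
    if match.orientation == "same":
        pos_b = pb
    else:
        if any(pb[k + 1] >= pb[k] for k in range(len(pb) - 1)) and not b.circular:
            return False  # reversed occurrence must run backwards in b
        pos_b = tuple(reversed(pb))
    return contiguous(a, match.positions_a, lab_a) and contiguous(b, pos_b, lab_b)


# ---------------------------------------------------------------------------
# set-level comparisons

def noncommon_genes(a: GeneOrder, b: GeneOrder):
    """Multiset-aware label difference: (only in a, only in b)."""
    ca, cb = Counter(a.labels), Counter(b.labels)
    only_a = sorted((ca - cb).elements())
    only_b = sorted((cb - ca).elements())
    return tuple(only_a), tuple(only_b)


def private_genes(a: GeneOrder, b: GeneOrder):
    """Presence-based difference: labels entirely absent from the other
    order (a duplicated gene with one copy in each genome is common)."""
    sa, sb = set(a.labels), set(b.labels)
    return tuple(sorted(sa - sb)), tuple(sorted(sb - sa))


def find_duplicates(order: GeneOrder) -> dict[str, int]:
    """Labels annotated with two or more copies."""
    return {l: n for l, n in Counter(order.labels).items() if n >= 2}


# ---------------------------------------------------------------------------
# TDRL

RETAIN = ("first", "second", "both")


@dataclass(frozen=True)
class TDRLEvent:
    """One tandem duplication-random loss event on a gene order.

    ``retention`` gives, per block position, which tandem copy survives
    ('both' leaves a duplicate).  ``result`` is the order produced on the
    shared label set; replaying the event must reproduce it exactly.
    """

    block: tuple[str, ...]
    block_start: int
    retention: tuple[str, ...]
    source: tuple[str, ...]
    result: tuple[str, ...]


def replay_tdrl(labels: tuple[str, ...], start: int, block_len: int,
                retention: tuple[str, ...]) -> tuple[str, ...]:
    """Apply a TDRL event to a label sequence."""
    block = labels[start:start + block_len]
    if len(block) != block_len or len(retention) != block_len:
        raise ValueError("block/retention length mismatch")
    copy1 = [l for l, r in zip(block, retention) if r in ("first", "both")]
    copy2 = [l for l, r in zip(block, retention) if r in ("second", "both")]
    return labels[:start] + tuple(copy1) + tuple(copy2) + labels[start + block_len:]


def _rotations(seq: tuple) -> set[tuple]:
    return {seq[i:] + seq[:i] for i in range(len(seq))}


def tdrl_candidates(a: GeneOrder, b: GeneOrder, max_block: int = 6,
                    max_replays: int = 2_000_000):
    """Exhaustive search for single TDRL events turning a into b on the
    shared label set.  Empty list when no single event explains b —
    including the case a == b (no event needed).
    """
    shared = set(a.labels) & set(b.labels)
    if len(shared) < 2:
        raise ValueError("orders share fewer than 2 labels")
    sa = tuple(l for l in a.labels if l in shared)
    sb = tuple(l for l in b.labels if l in shared)
    circular = a.circular and b.circular
    targets = _rotations(sb) if circular else {sb}
    if sa in targets:
        return []
    ca, cb = Counter(sa), Counter(sb)
    if any(cb[l] < ca[l] or cb[l] > ca[l] + 1 for l in ca | cb):
        return []  # single TDRL changes each copy number by at most +1

    n = len(sa)
    events = []
    replays = 0
    for L in range(1, min(max_block, n) + 1):
        for start in range(0, n - L + 1):
            for retention in product(RETAIN, repeat=L):
                replays += 1
                if replays > max_replays:
                    raise RuntimeError(
                        "TDRL search space exceeded; reduce max_block or "
                        "compare a smaller local window")
                result = replay_tdrl(sa, start, L, retention)
                if result in targets:
                    ev = TDRLEvent(sa[start:start + L], start, retention,
                                   sa, result)
                    events.append(ev)
    # drop no-op events (all-first / all-second with unchanged order)
    return [e for e in events if e.result != e.source]


@dataclass(frozen=True)
class AncestralDuplication:
    """A single ancestral tandem duplication explaining two sister
    orders through independent random losses."""

    ancestor: tuple[str, ...]
    block: tuple[str, ...]
    split_a: tuple[tuple[str, ...], tuple[str, ...]]
    split_b: tuple[tuple[str, ...], tuple[str, ...]]


def _is_subsequence(sub, seq) -> bool:
    it = iter(seq)
    return all(any(x == y for y in it) for x in sub)


def _decompose(middle, block):
    """Split middle into copy1+copy2, each a subsequence of block, with
    every block label retained at least once."""
    for cut in range(len(middle) + 1):
        m1, m2 = middle[:cut], middle[cut:]
        if not (_is_subsequence(m1, block) and _is_subsequence(m2, block)):
            continue
        if set(m1) | set(m2) == set(block):
            return m1, m2
    return None


def tdrl_ancestral_candidates(a: GeneOrder, b: GeneOrder,
                              max_block: int = 6):
    """Find single ancestral duplications whose two random-loss outcomes
    are the shared-label projections of a and b.

    The ancestor is reconstructed as common-prefix + block + common-
    suffix; every block permutation up to ``max_block`` labels is tried
    and each surviving candidate is validated by decomposition of both
    middles into two block subsequences.
    """
    shared = set(a.labels) & set(b.labels)
    sa = tuple(l for l in a.labels if l in shared)
    sb = tuple(l for l in b.labels if l in shared)
    if sa == sb:
        return []
    pre = 0
    while pre < min(len(sa), len(sb)) and sa[pre] == sb[pre]:
        pre += 1
    suf = 0
    while (suf < min(len(sa), len(sb)) - pre
           and sa[len(sa) - 1 - suf] == sb[len(sb) - 1 - suf]):
        suf += 1
    ma = sa[pre:len(sa) - suf]
    mb = sb[pre:len(sb) - suf]
    labels = set(ma) | set(mb)
    if not labels or len(labels) > max_block:
        return []
    out = []
    for block in permutations(sorted(labels)):
        da = _decompose(ma, block)
        db = _decompose(mb, block)
        if da is None or db is None:
            continue
        out.append(AncestralDuplication(
            ancestor=sa[:pre] + block + sa[len(sa) - suf:] if suf else sa[:pre] + block,
            block=block, split_a=da, split_b=db,
        ))
    return out
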