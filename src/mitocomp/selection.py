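"""Pairwise Ka/Ks estimation: Nei-Gojobori (1986) counting and the
Yang-Nielsen (2000) approximate method, with Fisher exact validation.

Both estimators consume a gap-free :class:`~mitocomp.alignment.CodonAlignment`
and report synonymous (S) and nonsynonymous (N) site totals, observed
synonymous/nonsynonymous differences (Sd, Nd) distributed over shortest
mutational pathways, and distance-corrected rates Ka = dN and Ks = dS.

NG86 treats all single-nucleotide changes as equally likely and corrects
the difference proportions with the one-parameter (Jukes-Cantor)
distance.  YN00 additionally estimates the transition/transversion rate
ratio kappa from nondegenerate and fourfold-degenerate sites, weights
mutational opportunity by kappa and by F3x4 equilibrium codon
frequencies, weights pathways by an omega-dependent rate product, and
corrects with the two-parameter (Kimura) distance, iterating the
omega-dependent weighting to convergence.

Pathways passing through stop codons are excluded; when every pathway
between a codon pair is blocked, that pair is skipped and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd
from scipy import stats

from .alignment import AlignmentScoring, CodonAlignment, codon_align
from .codes import CODONS, GeneticCode, genetic_code, is_transition
from .genomes import AnnotatedGenome, extract_cds

log = logging.getLogger(__name__)

NA = float("nan")


def _isna(x: float) -> bool:
    return x != x


@dataclass(frozen=True)
class KaKsResult:
    """Result of one pairwise Ka/Ks estimate."""

    method: str
    gene: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ka: float
    ks: float
    kappa: float = NA
    fisher_p: float = NA
    converged: bool = True
    flags: tuple[str, ...] = ()

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when Ks is zero or undefined."""
        if _isna(self.ka) or _isna(self.ks) or self.ks == 0.0:
            return NA
        return self.ka / self.ks

    def to_dict(self) -> dict:
        return {
            "method": self.method, "gene": self.gene, "n_codons": self.n_codons,
            "S": self.S, "N": self.N, "Sd": self.Sd, "Nd": self.Nd,
            "kappa": self.kappa, "Ka": self.ka, "Ks": self.ks,
            "KaKs": self.ratio, "fisher_p": self.fisher_p,
        }


# ---------------------------------------------------------------------------
# Pathway enumeration (shared by both estimators)

@dataclass(frozen=True)
class _Step:
    synonymous: bool
    transition: bool
    target: str      # codon reached by the step (forward direction)
    source: str


_PATH_CACHE: dict[tuple[int, str, str], tuple] = {}


def pathways(x: str, y: str, code: GeneticCode):
    """All shortest mutational pathways x -> y avoiding stop codons.

    Each pathway is a tuple of :class:`_Step`.  Returns an empty tuple
    when every ordering passes through a stop codon.
    """
    key = (code.table_id, x, y)
    hit = _PATH_CACHE.get(key)
    if hit is not None:
        return hit
    diff = [i for i in range(3) if x[i] != y[i]]
    paths = []
    for order in permutations(diff):
        cur = x
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + y[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            steps.append(_Step(
                synonymous=code.aa(cur) == code.aa(nxt),
                transition=is_transition(cur[pos], nxt[pos]),
                target=nxt, source=cur,
            ))
            cur = nxt
        if ok:
            paths.append(tuple(steps))
    result = tuple(paths)
    _PATH_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# NG86

def _ng86_codon_sites(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon, mutations to stops excluded
    from both numerator and denominator."""
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for p, _, nbr in code.single_change_neighbors(codon):
            if p != pos or code.is_stop(nbr):
                continue
            nonstop += 1
            if code.is_synonymous(codon, nbr):
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s


def kaks_ng86(caln: CodonAlignment, code: GeneticCode | int = 5) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    if isinstance(code, int):
        code = genetic_code(code)
    if caln.n_codons < 1:
        raise ValueError("empty codon alignment")
    flags: list[str] = []
    S = 0.0
    Sd = Nd = 0.0
    used = 0
    for c1, c2 in caln.pairs():
        if code.is_stop(c1) or code.is_stop(c2):
            log.warning("stop codon column %s/%s skipped", c1, c2)
            flags.append("stop_column_skipped")
            continue
        S += (_ng86_codon_sites(c1, code) + _ng86_codon_sites(c2, code)) / 2
        used += 1
        if c1 == c2:
            continue
        paths = pathways(c1, c2, code)
        if not paths:
            log.warning("all pathways %s->%s blocked by stops; pair skipped",
                        c1, c2)
            flags.append("blocked_pair_skipped")
            continue
        sd = nd = 0.0
        for p in paths:
            sd += sum(st.synonymous for st in p)
            nd += sum(not st.synonymous for st in p)
        Sd += sd / len(paths)
        Nd += nd / len(paths)
    N = 3.0 * used - S

    def jc(p: float) -> float:
        if p >= 0.75:
            flags.append("distance_undefined")
            return NA
        return -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(Sd / S) if S > 0 else NA
    ka = jc(Nd / N) if N > 0 else NA
    return KaKsResult("NG86", caln.gene, used, S, N, Sd, Nd, ka, ks,
                      flags=tuple(sorted(set(flags))))


# ---------------------------------------------------------------------------
# YN00

def f3x4_frequencies(caln: CodonAlignment, code: GeneticCode) -> dict[str, float]:
    """F3x4 equilibrium codon frequencies from both sequences jointly."""
    pos_counts = [dict.fromkeys("TCAG", 0) for _ in range(3)]
    for codon in list(caln.codons1) + list(caln.codons2):
        for i, b in enumerate(codon):
            pos_counts[i][b] += 1
    pos_freqs = []
    for counts in pos_counts:
        tot = sum(counts.values())
        pos_freqs.append({b: counts[b] / tot for b in "TCAG"})
    pi = {}
    for c in CODONS:
        if code.is_stop(c):
            continue
        pi[c] = pos_freqs[0][c[0]] * pos_freqs[1][c[1]] * pos_freqs[2][c[2]]
    tot = sum(pi.values())
    return {c: v / tot for c, v in pi.items()}


def _k80(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter distance and its transition/transversion
    components; returns (d, kappa_hat_component_A/B pair folded into d).
    Raises ValueError when the correction is undefined."""
    a = 1 - 2 * P - Q
    b = 1 - 2 * Q
    if a <= 0 or b <= 0:
        raise ValueError("K80 distance undefined")
    d = -0.5 * math.log(a) - 0.25 * math.log(b)
    return d, (-0.5 * math.log(a) + 0.25 * math.log(b), -0.5 * math.log(b))


def estimate_kappa(caln: CodonAlignment, code: GeneticCode) -> tuple[float, list[str]]:
    """Estimate kappa from nondegenerate and fourfold-degenerate sites.

    Sites are classified conservatively: a codon position counts only if
    it has the same degeneracy class (0-fold or 4-fold) in both codons of
    the column.  Each class yields a K80 kappa estimate; they are
    combined weighted by site counts.
    """
    flags: list[str] = []

    def degeneracy_class(codon: str, pos: int) -> int | None:
        syn = 0
        total = 0
        for p, _, nbr in code.single_change_neighbors(codon):
            if p != pos:
                continue
            total += 1
            if code.is_synonymous(codon, nbr):
                syn += 1
        if syn == 0:
            return 0
        if syn == total == 3:
            return 4
        return None

    sites = {0: 0, 4: 0}
    ts = {0: 0, 4: 0}
    tv = {0: 0, 4: 0}
    for c1, c2 in caln.pairs():
        if code.is_stop(c1) or code.is_stop(c2):
            continue
        for pos in range(3):
            d1 = degeneracy_class(c1, pos)
            if d1 is None or d1 != degeneracy_class(c2, pos):
                continue
            sites[d1] += 1
            if c1[pos] != c2[pos]:
                if is_transition(c1[pos], c2[pos]):
                    ts[d1] += 1
                else:
                    tv[d1] += 1

    estimates = {}
    for d in (0, 4):
        if sites[d] < 2:
            continue
        P, Q = ts[d] / sites[d], tv[d] / sites[d]
        try:
            _, (A, B) = _k80(P, Q)
        except ValueError:
            continue
        if B > 0:
            estimates[d] = max(2 * A / B, 1e-4)
    if not estimates:
        flags.append("kappa_default")
        return 2.0, flags
    w = {d: sites[d] for d in estimates}
    kappa = sum(estimates[d] * w[d] for d in estimates) / sum(w.values())
    return kappa, flags


def _yn00_sites(codons, code: GeneticCode, kappa: float,
                pi: dict[str, float]) -> float:
    """Synonymous site total with mutational opportunity weighted by the
    target codon frequency and kappa.

    The synonymous fraction is normalized globally over the sequence
    (3L * sum syn_w / sum tot_w) rather than codon by codon; under a
    GY94-style substitution process with heterogeneous per-codon total
    rates, the global normalization is what makes dN/dS consistent for
    the model's omega.
    """
    per_codon: dict[str, tuple[float, float]] = {}
    syn_sum = tot_sum = 0.0
    for codon in codons:
        st = per_codon.get(codon)
        if st is None:
            syn_w = tot_w = 0.0
            for pos, b, nbr in code.single_change_neighbors(codon):
                if code.is_stop(nbr):
                    continue
                w = pi.get(nbr, 0.0)
                if is_transition(codon[pos], b):
                    w *= kappa
                tot_w += w
                if code.is_synonymous(codon, nbr):
                    syn_w += w
            st = (syn_w, tot_w)
            per_codon[codon] = st
        syn_sum += st[0]
        tot_sum += st[1]
    return 3.0 * len(codons) * syn_sum / tot_sum if tot_sum > 0 else 0.0


def _weighted_differences(caln: CodonAlignment, code: GeneticCode,
                          kappa: float, omega: float, pi: dict[str, float],
                          flags: list[str]):
    """Pathway-weighted difference counts split by type.

    Pathway weight = product of step rates pi(target)*kappa^ts*omega^nonsyn,
    symmetrized over the two directions of the comparison.
    """
    sts = stv = nts = ntv = 0.0
    pair_counts: dict[tuple[str, str], int] = {}
    for c1, c2 in caln.pairs():
        if c1 == c2 or code.is_stop(c1) or code.is_stop(c2):
            continue
        pair_counts[(c1, c2)] = pair_counts.get((c1, c2), 0) + 1
    for (c1, c2), mult in pair_counts.items():
        fwd = pathways(c1, c2, code)
        rev = pathways(c2, c1, code)
        if not fwd or not rev:
            flags.append("blocked_pair_skipped")
            continue

        def rate(step: _Step) -> float:
            r = pi.get(step.target, 0.0)
            if step.transition:
                r *= kappa
            if not step.synonymous:
                r *= omega
            return r

        weights = []
        stats_per_path = []
        for pf, pr in zip(fwd, reversed_pairing(fwd, rev)):
            w = math.prod(rate(s) for s in pf) + math.prod(rate(s) for s in pr)
            weights.append(w)
            stats_per_path.append((
                sum(s.synonymous and s.transition for s in pf),
                sum(s.synonymous and not s.transition for s in pf),
                sum((not s.synonymous) and s.transition for s in pf),
                sum((not s.synonymous) and not s.transition for s in pf),
            ))
        total_w = sum(weights)
        if total_w <= 0:
            weights = [1.0] * len(weights)
            total_w = float(len(weights))
        for w, (a, b, c, d) in zip(weights, stats_per_path):
            frac = mult * w / total_w
            sts += frac * a
            stv += frac * b
            nts += frac * c
            ntv += frac * d
    return sts, stv, nts, ntv


def reversed_pairing(fwd, rev):
    """Match each forward pathway with its reverse (same positions in
    opposite order)."""
    def sig(path):
        return tuple(sorted(tuple(sorted((s.source, s.target))) for s in path))

    by_sig = {sig(p): p for p in rev}
    return [by_sig[sig(p)] for p in fwd]


def kaks_yn00(caln: CodonAlignment, code: GeneticCode | int = 5,
              tol: float = 1e-6, max_iter: int = 100,
              force_kappa: float | None = None,
              force_freqs: dict[str, float] | None = None) -> KaKsResult:
    """Yang-Nielsen (2000) approximate Ka/Ks.

    Steps: estimate kappa from degenerate-site classes; count S and N
    weighting each possible change by kappa and F3x4 codon frequencies;
    count Sd and Nd with omega-dependent pathway weighting; correct with
    the two-parameter distance; iterate omega to convergence.

    ``force_kappa`` / ``force_freqs`` bypass estimation (forcing kappa=1
    and uniform frequencies reduces the site and pathway weighting to
    the equal-weight NG86 scheme, leaving only the distance correction
    different).
    """
    if isinstance(code, int):
        code = genetic_code(code)
    if caln.n_codons < 1:
        raise ValueError("empty codon alignment")
    if caln.n_codons < 10:
        log.warning("%s: only %d aligned codons; YN00 is unreliable below 10",
                    caln.gene, caln.n_codons)
    flags: list[str] = []

    usable = [(c1, c2) for c1, c2 in caln.pairs()
              if not (code.is_stop(c1) or code.is_stop(c2))]
    n_used = len(usable)
    if n_used < caln.n_codons:
        flags.append("stop_column_skipped")
    identical = all(c1 == c2 for c1, c2 in usable)

    pi = force_freqs if force_freqs is not None else f3x4_frequencies(caln, code)
    if force_kappa is not None:
        kappa = force_kappa
    else:
        kappa, kflags = estimate_kappa(caln, code)
        flags += kflags

    if identical:
        S0 = _yn00_sites([c for c, _ in usable], code, kappa, pi)
        return KaKsResult("YN00", caln.gene, n_used, S0, 3.0 * n_used - S0,
                          0.0, 0.0, 0.0, 0.0, kappa=kappa,
                          flags=tuple(sorted(set(flags + ["identical"]))))

    S = (_yn00_sites([c for c, _ in usable], code, kappa, pi)
         + _yn00_sites([c for _, c in usable], code, kappa, pi)) / 2.0
    N = 3.0 * n_used - S

    omega = 1.0
    converged = False
    ka = ks = NA
    Sd = Nd = 0.0
    for _ in range(max_iter):
        sts, stv, nts, ntv = _weighted_differences(
            caln, code, kappa, omega, pi, flags)
        Sd, Nd = sts + stv, nts + ntv
        try:
            ds, _ = _k80(sts / S, stv / S) if S > 0 else (NA, None)
        except ValueError:
            ds = NA
        try:
            dn, _ = _k80(nts / N, ntv / N) if N > 0 else (NA, None)
        except ValueError:
            dn = NA
        ka, ks = dn, ds
        if _isna(ds) or _isna(dn):
            flags.append("distance_undefined")
            break
        new_omega = dn / ds if ds > 0 else (99.0 if dn > 0 else 1.0)
        new_omega = min(max(new_omega, 1e-4), 99.0)
        if abs(new_omega - omega) <= tol * max(omega, 1e-8):
            omega = new_omega
            converged = True
            break
        omega = new_omega
    if not converged and "distance_undefined" not in flags:
        flags.append("not_converged")
        log.warning("%s: YN00 omega iteration did not converge", caln.gene)
    return KaKsResult("YN00", caln.gene, n_used, S, N, Sd, Nd, ka, ks,
                      kappa=kappa, converged=converged,
                      flags=tuple(sorted(set(flags))))


# ---------------------------------------------------------------------------
# Fisher exact validation

def fisher_kaks(result: KaKsResult) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    {synonymous, nonsynonymous} x {differences, sites - differences}.

    Real-valued site and difference counts are rounded to the nearest
    integer for the hypergeometric support; the two-sided p sums all
    tables with probability <= that of the observed table.
    """
    if any(_isna(v) for v in (result.S, result.N, result.Sd, result.Nd)):
        raise ValueError("Fisher test needs finite S, N, Sd, Nd")
    sd, nd = round(result.Sd), round(result.Nd)
    s_rest, n_rest = round(result.S) - sd, round(result.N) - nd
    table = [[sd, s_rest], [nd, n_rest]]
    if min(sd, nd, s_rest, n_rest) < 0:
        raise ValueError(f"negative cell after rounding: {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def with_fisher(result: KaKsResult) -> KaKsResult:
    from dataclasses import replace

    if any(_isna(v) for v in (result.S, result.N)):
        return result
    return replace(result, fisher_p=fisher_kaks(result))


# ---------------------------------------------------------------------------
# Pairwise matrix over genomes

METHODS = {"NG86": kaks_ng86, "YN00": kaks_yn00}


def pairwise_kaks_matrix(query: AnnotatedGenome, references,
                         genes=None, method: str = "YN00",
                         code: GeneticCode | int = 5,
                         scoring: AlignmentScoring | None = None,
                         fisher: bool = True) -> pd.DataFrame:
    """One Ka/Ks row per (gene, reference genome) pair.

    Duplicated genes contribute their first copy (genome order).  A gene
    missing from a reference yields a row of NAs with the reason.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    if method not in METHODS:
        raise KeyError(f"method must be one of {sorted(METHODS)}")
    estimator = METHODS[method]

    def cds_map(genome):
        out = {}
        for cds in extract_cds(genome, code):
            if cds.copy_index == 1:
                out[cds.name] = cds
        return out

    qmap = cds_map(query)
    rows = []
    any_shared = False
    for ref in references:
        rmap = cds_map(ref)
        wanted = genes if genes is not None else sorted(set(qmap) & set(rmap))
        for gene in wanted:
            base = {"gene": gene, "pair": f"{query.id} vs {ref.id}"}
            if gene not in qmap or gene not in rmap:
                rows.append({**base, "method": method, "reason": "missing homolog"})
                continue
            any_shared = True
            caln = codon_align(qmap[gene].sequence, rmap[gene].sequence,
                               code, gene=gene, scoring=scoring)
            res = estimator(caln, code)
            if fisher and not any(_isna(v) for v in (res.S, res.N)):
                res = with_fisher(res)
            rows.append({**base, **{k: v for k, v in res.to_dict().items()
                                    if k != "gene"}})
    if not any_shared:
        raise ValueError("no shared genes between query and references")
    return pd.DataFrame(rows)
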