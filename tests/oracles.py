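"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the library's code paths: translation goes through
Bio.Seq, pathway enumeration is recursive rather than permutation-based, and
hypergeometric tails are summed with exact rational arithmetic.
"""
from fractions import Fraction
from math import comb

from Bio.Seq import Seq


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    """Fractional synonymous site count (changes to stops = nonsynonymous)."""
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if _aa(alt) == aa and _aa(alt) != "*":
                s += 1.0 / 3.0
    return s


def _paths(c1: str, c2: str, allow_stops: bool):
    """All stepwise mutation paths c1 -> c2 as (syn, nonsyn) step counts."""
    if c1 == c2:
        return [(0.0, 0.0)]
    results = []
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        mid = c1[:pos] + c2[pos] + c1[pos + 1:]
        if _aa(mid) == "*" and not allow_stops and mid != c2:
            continue
        step_syn = (_aa(c1) == _aa(mid) and _aa(c1) != "*" and _aa(mid) != "*")
        for syn, nsyn in _paths(mid, c2, allow_stops):
            results.append((syn + (1.0 if step_syn else 0.0),
                            nsyn + (0.0 if step_syn else 1.0)))
    return results


def oracle_ng86(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(ps, pn, S, N) by exhaustive per-codon pathway averaging."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        ca, cb = seq1[i:i + 3], seq2[i:i + 3]
        sa, sb = oracle_sites(ca), oracle_sites(cb)
        S += (sa + sb) / 2.0
        N += (3.0 - sa + 3.0 - sb) / 2.0
        paths = [p for p in _paths(ca, cb, allow_stops=False)]
        if not paths:
            paths = _paths(ca, cb, allow_stops=True)
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
    return Sd / S, Nd / N, S, N


def oracle_hypergeom_upper_tail(k: int, n_pop: int, k_pop: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeom(n_pop, k_pop, n_draw), exact summation."""
    total = Fraction(0)
    denom = comb(n_pop, n_draw)
    for x in range(k, min(k_pop, n_draw) + 1):
        total += Fraction(comb(k_pop, x) * comb(n_pop - k_pop, n_draw - x), denom)
    return float(total)


def oracle_fisher_2x2_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for table [[a, b], [c, d]]."""
    return oracle_hypergeom_upper_tail(a, a + b + c + d, a + b, a + c)


def oracle_effect(codon: str, pos: int, alt: str) -> str:
    """Consequence of one base change by direct translation."""
    alt_codon = codon[:pos] + alt + codon[pos + 1:]
    aa0, aa1 = _aa(codon), _aa(alt_codon)
    if aa0 == "*" and aa1 != "*":
        return "stop_lost"
    if aa1 == "*":
        return "nonsense"
    return "synonymous" if aa0 == aa1 else "missense"


def oracle_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Sliding-window canonical k-mer recount by string comparison."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) - set("ACGT"):
            continue
        rc = kmer.translate(comp)[::-1]
        canon = min(kmer, rc)
        counts[canon] = counts.get(canon, 0) + 1
    return counts
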