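"""Genetic-code tables and Nei–Gojobori (NG86) codon machinery.

Shared by the simulator (codon-aware divergence), the Ks estimator and the
variant-effect annotator so that all three agree on what "synonymous" means.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
_STANDARD = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: 4-fold degenerate codon families used by the simulator: every third-position
#: change is synonymous and no single-base change can produce a stop codon
#: (first bases G/A/C, second bases C/T; stops all require T at position 1 and
#: A/G at position 2).
FOURFOLD_FAMILY_CODONS: tuple[str, ...] = tuple(
    pre + b for pre in ("GC", "GT", "AC", "CC") for b in BASES
)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


@lru_cache(maxsize=None)
def syn_fractions(codon: str) -> tuple[float, float, float]:
    """Fractional synonymous site count at each codon position.

    NG86 convention: of the three possible changes at a position, the fraction
    that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if not is_stop(alt) and CODON_TO_AA[alt] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    s = sum(syn_fractions(codon))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averages over all orderings of the differing positions, excluding
    pathways that pass through a stop codon.  If every pathway is blocked
    (possible only for 3-fold differences), all pathways are used and steps
    into/out of stops count as nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops: bool):
        syn = nsyn = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if is_stop(nxt) and not allow_stops:
                return None
            if (not is_stop(cur) and not is_stop(nxt)
                    and CODON_TO_AA[cur] == CODON_TO_AA[nxt]):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        return syn, nsyn

    paths = [walk(order, False) for order in itertools.permutations(diff)]
    paths = [p for p in paths if p is not None]
    if not paths:
        paths = [walk(order, True) for order in itertools.permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); nan if p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def validate_cds(cds: str, name: str = "CDS") -> None:
    if len(cds) % 3 != 0:
        raise ValueError(f"{name} length {len(cds)} not divisible by 3")
    for i in range(0, len(cds), 3):
        if is_stop(cds[i:i + 3]):
            raise ValueError(f"{name} contains internal stop codon at codon {i // 3}")


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """NG86 fractional (synonymous, nonsynonymous) site counts over a CDS."""
    s = n = 0.0
    for i in range(0, len(cds), 3):
        si, ni = codon_sites(cds[i:i + 3])
        s += si
        n += ni
    return s, n
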