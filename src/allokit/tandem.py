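"""Tandem duplication arrays, GO enrichment and gene-set overlap tests.

Tandem arrays are maximal runs of same-family genes on one chromosome with at
most ``max_gap`` intervening genes between consecutive members (an
MCScanX-style convention).  Enrichment uses the one-sided Fisher exact
(hypergeometric upper tail) per term with Bonferroni, Sidak, Holm and
Benjamini-Hochberg FDR adjustments over the tested terms.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import Gene


@dataclass
class TandemArray:
    chromosome: str
    family: str
    members: list[str]              # ordered gene ids
    span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def find_tandem_arrays(genes: list[Gene], max_gap: int = 10) -> list[TandemArray]:
    """Merge same-family genes separated by <= max_gap intervening genes.

    ``genes`` must be ordered by (chromosome, start); arrays have >= 2 members.
    """
    for prev, cur in zip(genes, genes[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise ValueError("genes must be ordered by chromosome and start")
    arrays: list[TandemArray] = []
    open_runs: dict[str, tuple[list[Gene], int]] = {}   # family -> (members, last index)
    chrom = None
    for idx, g in enumerate(genes):
        if g.chrom != chrom:
            _flush(open_runs, arrays)
            open_runs, chrom = {}, g.chrom
        if g.family in open_runs:
            members, last = open_runs[g.family]
            if idx - last - 1 <= max_gap:
                members.append(g)
                open_runs[g.family] = (members, idx)
            else:
                _close(members, arrays)
                open_runs[g.family] = ([g], idx)
        else:
            open_runs[g.family] = ([g], idx)
    _flush(open_runs, arrays)
    return arrays


def _close(members: list[Gene], arrays: list[TandemArray]) -> None:
    if len(members) >= 2:
        arrays.append(TandemArray(
            chromosome=members[0].chrom, family=members[0].family,
            members=[g.gene_id for g in members],
            span=(members[0].start, members[-1].end)))


def _flush(open_runs, arrays) -> None:
    for members, _ in open_runs.values():
        _close(members, arrays)
    arrays.sort(key=lambda a: (a.chromosome, a.span[0]))


def tandem_gene_ids(arrays: list[TandemArray]) -> set[str]:
    """All genes counted as tandem duplicates."""
    return {gid for a in arrays for gid in a.members}


ADJUST_METHODS = {"bonferroni": "bonferroni", "sidak": "sidak",
                  "holm": "holm", "fdr": "fdr_bh"}


def go_enrichment(study: set[str], population: set[str],
                  term_map: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each term in the study set.

    Returns one row per term with the 2x2 counts, raw p (hypergeometric upper
    tail) and all four adjusted p-values, sorted by raw p.
    """
    stray = study - population
    if stray:
        raise ValueError(f"study genes missing from population, e.g. "
                         f"{sorted(stray)[:3]}")
    n_pop, n_study = len(population), len(study)
    rows = []
    for term in sorted(term_map):
        hits_pop = term_map[term] & population
        k_pop = len(hits_pop)
        k_study = len(hits_pop & study)
        # P(X >= k_study) for X ~ Hypergeom(n_pop, k_pop, n_study)
        p = float(stats.hypergeom.sf(k_study - 1, n_pop, k_pop, n_study))
        rows.append((term, k_study, n_study, k_pop, n_pop, p))
    df = pd.DataFrame(rows, columns=["term", "study_hits", "study_size",
                                     "population_hits", "population_size",
                                     "p_raw"])
    import numpy as np
    with np.errstate(divide="ignore"):      # sidak hits log(0) at p = 1
        for name, method in ADJUST_METHODS.items():
            df[f"p_{name}"] = (multipletests(df["p_raw"], method=method)[1]
                               if len(df) else [])
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)


def lineage_specific_terms(term_sets: dict[str, set[str]]) -> dict[str, int]:
    """Venn partition counts over per-lineage term sets.

    Keys are '+'-joined lineage combinations (e.g. 'EU', 'EU+CN'); values count
    terms present in exactly that combination.  Sizes sum to |union|.
    """
    if len(term_sets) < 2:
        raise ValueError("need at least two lineages")
    lineages = sorted(term_sets)
    partition: dict[str, int] = {}
    for r in range(1, len(lineages) + 1):
        for combo in combinations(lineages, r):
            inside = set.intersection(*(term_sets[l] for l in combo))
            outside = set.union(*(term_sets[l] for l in lineages if l not in combo),
                                ) if len(combo) < len(lineages) else set()
            partition["+".join(combo)] = len(inside - outside)
    return partition


@dataclass
class OverlapResult:
    overlap: int
    fraction: float                 # overlap / |set1|
    p_value: float
    odds_ratio: float


def set_overlap_test(set1: set[str], set2: set[str],
                     universe_size: int) -> OverlapResult:
    """Fisher exact test of the overlap between two gene sets in a universe."""
    if universe_size <= 0:
        raise ValueError("universe must be nonempty")
    if len(set1 | set2) > universe_size:
        raise ValueError("sets exceed universe size")
    k = len(set1 & set2)
    table = [[k, len(set1) - k],
             [len(set2) - k, universe_size - len(set1) - len(set2) + k]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    fraction = k / len(set1) if set1 else 0.0
    return OverlapResult(overlap=k, fraction=fraction,
                         p_value=float(p), odds_ratio=float(odds))
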