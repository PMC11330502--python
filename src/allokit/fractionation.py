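"""Biased fractionation: retention tables, loss-bias tests, window profiles.

After allopolyploidy the genome sheds redundant duplicates; when one subgenome
loses systematically more genes than the other the polyploid shows subgenome
dominance.  Retention is scored against an ancestor (or outgroup) gene order:
each ancestral gene is flagged retained/lost per subgenome, losses are tested
against a 50:50 expectation, and retained fractions are profiled in sliding
windows of ancestor genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RetentionTable:
    table: pd.DataFrame             # ancestor_gene, retained_in_A, retained_in_D
    both: int
    a_only: int
    d_only: int
    neither: int

    @property
    def total(self) -> int:
        return len(self.table)

    def check_conservation(self) -> None:
        if self.both + self.a_only + self.d_only + self.neither != self.total:
            raise AssertionError("retention classes do not sum to total genes")


@dataclass
class Chi2Result:
    statistic: float
    p_value: float
    df: int


def build_retention(ancestor_order: list[str], syntelogs_a: set[str],
                    syntelogs_d: set[str]) -> RetentionTable:
    """Flag each ancestor gene as retained in A and/or D and aggregate."""
    known = set(ancestor_order)
    for name, s in (("A", syntelogs_a), ("D", syntelogs_d)):
        unknown = s - known
        if unknown:
            raise ValueError(f"syntelog set {name} references unknown ancestor "
                             f"genes, e.g. {sorted(unknown)[:3]}")
    df = pd.DataFrame({
        "ancestor_gene": list(ancestor_order),
        "retained_in_A": [g in syntelogs_a for g in ancestor_order],
        "retained_in_D": [g in syntelogs_d for g in ancestor_order]})
    a, d = df["retained_in_A"].to_numpy(), df["retained_in_D"].to_numpy()
    rt = RetentionTable(table=df,
                        both=int((a & d).sum()), a_only=int((a & ~d).sum()),
                        d_only=int((~a & d).sum()), neither=int((~a & ~d).sum()))
    rt.check_conservation()
    return rt


def loss_bias_test(a_only: int, d_only: int) -> Chi2Result:
    """Goodness-of-fit chi-square of the two exclusive-loss counts vs 50:50.

    ``a_only`` genes survive only in A (lost from D) and vice versa; under
    unbiased fractionation both categories are equally likely (df = 1).
    """
    if a_only < 0 or d_only < 0:
        raise ValueError("counts must be nonnegative")
    total = a_only + d_only
    if total == 0:
        raise ValueError("cannot test bias with zero exclusive losses")
    expected = total / 2.0
    chi2 = (a_only - expected) ** 2 / expected + (d_only - expected) ** 2 / expected
    return Chi2Result(statistic=float(chi2),
                      p_value=float(stats.chi2.sf(chi2, df=1)), df=1)


def loss_bias_test_2x2(retained_a: int, lost_a: int,
                       retained_d: int, lost_d: int) -> Chi2Result:
    """Contingency variant: retained/lost x subgenome, chi-square without
    continuity correction (df = 1)."""
    table = np.array([[retained_a, lost_a], [retained_d, lost_d]])
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(chi2), p_value=float(p), df=int(df))


def retention_windows(table: RetentionTable,
                      ancestor_chromosomes: dict[str, list[str]],
                      window: int = 100, step: int = 10) -> pd.DataFrame:
    """Sliding-window retained fractions per subgenome along ancestor order.

    Returns one row per (ancestor chromosome, window) with the retained
    fraction in each subgenome; the terminal window may hold fewer genes.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    flags = table.table.set_index("ancestor_gene")
    rows = []
    for chrom, order in sorted(ancestor_chromosomes.items()):
        if window > len(order):
            raise ValueError(f"window {window} exceeds {len(order)} genes on {chrom}")
        a = flags.loc[order, "retained_in_A"].to_numpy(float)
        d = flags.loc[order, "retained_in_D"].to_numpy(float)
        starts = list(range(0, len(order), step))
        for w, s in enumerate(starts):
            e = min(s + window, len(order))
            rows.append((chrom, w, s, e, e - s,
                         float(a[s:e].mean()), float(d[s:e].mean())))
            if e == len(order):
                break
    return pd.DataFrame(rows, columns=["chromosome", "window", "start", "end",
                                       "n_genes", "fraction_A", "fraction_D"])
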