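"""Coding-consequence annotation and per-class nucleotide diversity (πN, πS).

Variants inside annotated CDS are placed in codon context (strand-aware) and
classified by the genetic code: synonymous -> LOW impact, amino-acid change ->
MODERATE, stop gained/lost -> HIGH; MODERATE and HIGH sites are flagged
deleterious.  π per class is single-individual heterozygosity: each variant
site contributes 2p(1-p) * n/(n-1) with p the within-individual allele
fraction estimated from read depths and n = 2 allele draws, divided by the
NG86 fractional count of callable sites of that class over all CDS — the
denominator that makes πN/πS comparable across selective regimes.
"""
from __future__ import annotations

from dataclasses import dataclass
from bisect import bisect_right

import numpy as np
import pandas as pd

from ._codons import CODON_TO_AA, is_stop, ng86_site_counts
from .genome import AnnotatedGenome

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

IMPACT_OF = {"synonymous": "LOW", "missense": "MODERATE", "nonsense": "HIGH",
             "stop_lost": "HIGH", "intergenic": "NONE"}
DELETERIOUS_IMPACTS = frozenset({"HIGH", "MODERATE"})


@dataclass
class DiversitySummary:
    pi_nonsyn: float
    pi_syn: float
    ratio: float | None             # None when pi_syn == 0
    syn_sites: float                # callable synonymous sites (NG86)
    nonsyn_sites: float
    n_syn_variants: int
    n_nonsyn_variants: int


def classify_codon_change(codon: str, pos_in_codon: int, alt_base: str) -> str:
    """Consequence of a single-base change, by the standard genetic code."""
    alt_codon = codon[:pos_in_codon] + alt_base + codon[pos_in_codon + 1:]
    if is_stop(codon) and not is_stop(alt_codon):
        return "stop_lost"
    if is_stop(alt_codon):
        return "nonsense"
    return "synonymous" if CODON_TO_AA[codon] == CODON_TO_AA[alt_codon] else "missense"


def annotate_effects(sites: pd.DataFrame, genome: AnnotatedGenome) -> pd.DataFrame:
    """Annotate variant sites with coding consequence and impact.

    ``sites`` needs chrom, pos (1-based), ref, alt columns; the ref allele
    must match the genome.  Returns the table with gene, consequence, impact
    and deleterious columns appended (intergenic sites get impact NONE).
    """
    by_chrom: dict[str, tuple[list[int], list]] = {}
    for chrom in genome.chromosomes:
        genes = genome.genes_on(chrom)
        by_chrom[chrom] = ([g.start for g in genes], genes)

    out = sites.copy()
    gene_col, cons_col = [], []
    for chrom, pos1, ref, alt in zip(sites["chrom"], sites["pos"],
                                     sites["ref"], sites["alt"]):
        pos = int(pos1) - 1
        genome_base = genome.chromosomes[chrom][pos]
        if genome_base != ref:
            raise ValueError(f"ref allele {ref} at {chrom}:{pos1} does not "
                             f"match genome base {genome_base}")
        starts, genes = by_chrom[chrom]
        gi = bisect_right(starts, pos) - 1
        gene = genes[gi] if gi >= 0 and pos < genes[gi].end else None
        if gene is None:
            gene_col.append("")
            cons_col.append("intergenic")
            continue
        if gene.strand == "+":
            cds_i = pos - gene.start
            alt_cds = alt
        else:
            cds_i = gene.end - 1 - pos
            alt_cds = alt.translate(_COMPLEMENT)
        codon = gene.cds[3 * (cds_i // 3):3 * (cds_i // 3) + 3]
        gene_col.append(gene.gene_id)
        cons_col.append(classify_codon_change(codon, cds_i % 3, alt_cds))
    out["gene"] = gene_col
    out["consequence"] = cons_col
    out["impact"] = [IMPACT_OF[c] for c in cons_col]
    out["deleterious"] = [i in DELETERIOUS_IMPACTS for i in out["impact"]]
    return out


def pi_by_class(annotated: pd.DataFrame, genome: AnnotatedGenome,
                n_alleles: int = 2) -> DiversitySummary:
    """πN, πS and their ratio from annotated sites with read depths.

    Callable-site denominators are NG86 fractional synonymous/nonsynonymous
    site counts over all annotated CDS; deleterious-candidate classes
    (missense, nonsense, stop_lost) contribute to πN, synonymous sites to πS.
    """
    syn_sites = nonsyn_sites = 0.0
    for g in genome.genes:
        s, n = ng86_site_counts(g.cds)
        syn_sites += s
        nonsyn_sites += n
    if syn_sites == 0:
        raise ValueError("no callable synonymous sites in the annotation")

    total = (annotated["ref_depth"] + annotated["alt_depth"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, annotated["alt_depth"].to_numpy(float) / total, 0.0)
    contrib = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1)

    is_syn = (annotated["consequence"] == "synonymous").to_numpy()
    is_non = annotated["consequence"].isin(["missense", "nonsense", "stop_lost"]).to_numpy()
    pi_s = float(contrib[is_syn].sum()) / syn_sites
    pi_n = float(contrib[is_non].sum()) / nonsyn_sites
    ratio = (pi_n / pi_s) if pi_s > 0 else None
    return DiversitySummary(pi_nonsyn=pi_n, pi_syn=pi_s, ratio=ratio,
                            syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
                            n_syn_variants=int(is_syn.sum()),
                            n_nonsyn_variants=int(is_non.sum()))


def ratio_table(summaries: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Accession table of πN, πS (6 decimals) and πN/πS (2 decimals).

    ``summaries`` maps accession -> (pi_nonsyn, pi_syn); the ratio is computed
    from the unrounded values and rounded last, matching how such tables are
    normally printed.
    """
    if not summaries:
        raise ValueError("need at least one accession")
    rows = []
    for name, (pi_n, pi_s) in summaries.items():
        if pi_s <= 0:
            raise ValueError(f"{name}: ratio undefined with pi_syn = {pi_s}")
        rows.append((name, round(pi_n, 6), round(pi_s, 6), round(pi_n / pi_s, 2)))
    return pd.DataFrame(rows, columns=["accession", "pi_nonsynonymous",
                                       "pi_synonymous", "pi_n_over_pi_s"])
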