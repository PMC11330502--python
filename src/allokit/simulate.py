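"""Synthetic allopolyploid genomes, B chromosomes and sequencing observations.

The generator emulates the statistical structure an allotetraploid genome
analysis assumes: an ancestral gene order duplicated into two subgenomes (A, D)
with a tunable expected synonymous divergence Ks, biased gene loss, tandem
duplications, subgenome-specific repeat families, a B chromosome mosaicked
from 300-bp main-chromosome fragments, and per-site allele-depth / per-window
read-depth observations for an individual of chosen ploidy and B dosage.

Coding sequences are built from 4-fold-degenerate codon families (Ala, Val,
Thr, Pro) behind an ATG start, so third positions evolve as an exact
Jukes-Cantor process at rate Ks and first/second positions at omega*Ks; no
single-base change can create a stop codon, which keeps every simulated CDS
translatable and makes the synonymous divergence calibration exact.

All randomness flows from one seeded generator per operation
(``default_rng([seed, stage])`` with stage 1, 2, 3 for the three operations);
identical (config, seed) therefore give byte-identical serialized outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._codons import FOURFOLD_FAMILY_CODONS
from .genome import AnnotatedGenome, Gene, GroundTruth, MaskInterval, revcomp

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: maximum Ks for which the expected synonymous difference fraction stays
#: clearly below the Jukes-Cantor singularity at 3/4
MAX_KS = 3.2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; defaults mirror the analysed system.

    ``subgenome_divergence_ks`` is the expected synonymous substitutions per
    synonymous site between homoeologs (the inter-subgenome Ks peak of the
    reference genome sits at 0.2); loss fractions encode biased fractionation;
    ``ploidy`` is the homoeologous copy count of the sequenced individual
    (4 = allotetraploid, 6 = allohexaploid).
    """

    n_chromosome_pairs: int = 12
    genes_per_chromosome: int = 420
    codons_per_gene: int = 100
    subgenome_divergence_ks: float = 0.2
    omega: float = 0.5
    loss_fraction_A: float = 0.15
    loss_fraction_D: float = 0.10
    tandem_rate: float = 0.05
    repeat_family_fold: float = 2.0
    b_source_fraction: float = 0.25
    ploidy: int = 4
    b_copies: int = 2
    mean_depth: float = 60.0
    heterozygosity_syn: float = 0.003
    heterozygosity_nonsyn: float = 0.0015
    seed: int = 42
    # structural knobs (desk-scale defaults, see docs/methods.md)
    repeats_per_chromosome: int = 50
    repeat_length: int = 500
    repeat_divergence: float = 0.0
    intergenic_length: int = 200
    tandem_spacer: int = 60
    b_length: int = 120_000
    b_fragment: int = 300
    b_noise: float = 0.02
    mismap_rate: float = 0.01
    coverage_window: int = 1000
    artifact_length: int = 10_000
    artifact_fold: float = 8.0
    repeat_depth_fold: float = 5.0

    def __post_init__(self):
        for name in ("n_chromosome_pairs", "genes_per_chromosome",
                     "codons_per_gene", "repeats_per_chromosome",
                     "repeat_length", "intergenic_length", "b_length",
                     "b_fragment", "coverage_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("loss_fraction_A", "loss_fraction_D"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.subgenome_divergence_ks < 0:
            raise ValueError("subgenome_divergence_ks must be >= 0")
        if self.subgenome_divergence_ks > MAX_KS:
            raise ValueError(
                f"subgenome_divergence_ks={self.subgenome_divergence_ks} too "
                f"high: expected synonymous differences approach the 3/4 "
                f"Jukes-Cantor saturation bound (max {MAX_KS})")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must be in (0, 1]")
        if self.repeat_family_fold < 1.0:
            raise ValueError("repeat_family_fold must be >= 1")
        if not 0.0 <= self.b_source_fraction <= 1.0:
            raise ValueError("b_source_fraction must be in [0, 1]")
        if self.ploidy not in (4, 6):
            raise ValueError(f"ploidy must be 4 or 6, got {self.ploidy}")
        if self.b_copies < 0:
            raise ValueError("b_copies must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


# ----------------------------------------------------------------- utilities
def _arr_to_seq(arr: np.ndarray) -> str:
    return _BASE_ARR[arr].tobytes().decode()


def _seq_to_arr(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def _random_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _jc_probability(d: float) -> float:
    """Probability that a site differs from its ancestor after branch d."""
    return 0.75 * (1.0 - float(np.exp(-4.0 * d / 3.0)))


def _jc_branch(rng: np.random.Generator, arr: np.ndarray, d: float,
               positions: np.ndarray | None = None) -> None:
    """Apply a Jukes-Cantor transition of branch length d in place."""
    if d <= 0:
        return
    idx = np.arange(arr.size) if positions is None else positions
    hit = idx[rng.random(idx.size) < _jc_probability(d)]
    if hit.size:
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=hit.size)) % 4


def _random_cds(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    codons = rng.integers(0, len(FOURFOLD_FAMILY_CODONS), size=n_codons - 1)
    body = "".join(FOURFOLD_FAMILY_CODONS[i] for i in codons)
    return _seq_to_arr("ATG" + body)


# stop codons in 2-bit code (A=0,C=1,G=2,T=3): TAA, TAG, TGA
def _fix_stops(arr: np.ndarray, ancestor: np.ndarray) -> None:
    """Revert second codon positions of stop codons created by double hits."""
    c0, c1, c2 = arr[3::3], arr[4::3], arr[5::3]
    stop = (c0 == 3) & (((c1 == 0) & ((c2 == 0) | (c2 == 2)))
                        | ((c1 == 2) & (c2 == 0)))
    if stop.any():
        c1[stop] = ancestor[4::3][stop]


def _diverge_cds(rng: np.random.Generator, ancestor: np.ndarray,
                 ks_branch: float, omega: float) -> np.ndarray:
    arr = ancestor.copy()
    pos = np.arange(3, arr.size)
    syn = pos[pos % 3 == 2]
    nonsyn = pos[pos % 3 != 2]
    _jc_branch(rng, arr, ks_branch, syn)
    _jc_branch(rng, arr, omega * ks_branch, nonsyn)
    _fix_stops(arr, ancestor)
    return arr


def _codon_change_classes(codon: str) -> np.ndarray:
    """(3, 4) table of single-change consequences: 0 ref, 1 syn, 2 missense,
    3 nonsense/stop-affecting."""
    from ._codons import CODON_TO_AA, is_stop
    tab = np.zeros((3, 4), dtype=np.int8)
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for bi, b in enumerate("ACGT"):
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if is_stop(alt):
                tab[pos, bi] = 3
            elif CODON_TO_AA[alt] == aa:
                tab[pos, bi] = 1
            else:
                tab[pos, bi] = 2
    return tab


# ------------------------------------------------------- main chromosome set
def simulate_allopolyploid(config: SimulationConfig) -> tuple[AnnotatedGenome, GroundTruth]:
    """Build an allotetraploid genome (subgenomes A and D) plus ground truth.

    The ancestor gene order is duplicated; each branch receives half the
    configured divergence so that homoeolog pairs have expected synonymous
    divergence ``subgenome_divergence_ks`` and nonsynonymous divergence
    ``omega`` times that.  Genes are deleted per subgenome at the configured
    loss fractions, tandem copies are inserted adjacent to their source, and
    each subgenome carries its own repeat family at ``repeat_family_fold``
    enrichment over the other subgenome.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_chrom = config.n_chromosome_pairs
    n_genes = config.genes_per_chromosome

    # --- ancestor: per chromosome, gene CDS arrays and intergenic spacers
    anc_genes: list[list[np.ndarray]] = []
    anc_spacers: list[list[np.ndarray]] = []
    for _c in range(n_chrom):
        anc_genes.append([_random_cds(rng, config.codons_per_gene)
                          for _ in range(n_genes)])
        anc_spacers.append([_random_arr(rng, config.intergenic_length)
                            for _ in range(n_genes + 1)])

    repeat_consensus = {label: _arr_to_seq(_random_arr(rng, config.repeat_length))
                        for label in ("A", "D")}

    genome = AnnotatedGenome(chromosomes={})
    truth = GroundTruth(n_ancestor_genes=n_chrom * n_genes,
                        repeat_consensus=repeat_consensus)
    retained: dict[str, dict[tuple[int, int], str]] = {"A": {}, "D": {}}

    ks_branch = config.subgenome_divergence_ks / 2.0
    n_own = config.repeats_per_chromosome
    n_other = int(round(n_own / config.repeat_family_fold))

    for label, loss in (("A", config.loss_fraction_A), ("D", config.loss_fraction_D)):
        other = "D" if label == "A" else "A"
        own_rep = _seq_to_arr(repeat_consensus[label])
        oth_rep = _seq_to_arr(repeat_consensus[other])
        for c in range(n_chrom):
            chrom = f"{label}{c + 1:02d}"
            deleted = rng.random(n_genes) < loss
            tandems = rng.poisson(config.tandem_rate, size=n_genes)
            # repeats scattered over intergenic slots (several may share a
            # slot), own family first
            slots = rng.integers(0, n_genes + 1, size=n_own + n_other)
            by_slot: dict[int, list[np.ndarray]] = {}
            for j, slot in enumerate(slots):
                src = own_rep if j < n_own else oth_rep
                copy = src.copy()
                _jc_branch(rng, copy, config.repeat_divergence)
                by_slot.setdefault(int(slot), []).append(copy)

            parts: list[str] = []
            cursor = 0
            chrom_genes: list[Gene] = []
            chrom_masks: list[MaskInterval] = []

            def emit(arr: np.ndarray) -> tuple[int, int]:
                nonlocal cursor
                start = cursor
                parts.append(_arr_to_seq(arr))
                cursor += arr.size
                return start, cursor

            def emit_gene(gene_id: str, idx: int, cds_arr: np.ndarray) -> Gene:
                strand = "+" if idx % 2 == 0 else "-"
                cds = _arr_to_seq(cds_arr)
                placed = cds if strand == "+" else revcomp(cds)
                start, end = emit(_seq_to_arr(placed))
                return Gene(gene_id=gene_id, chrom=chrom, start=start, end=end,
                            strand=strand, cds=cds,
                            family=f"fam{c + 1:02d}_{idx + 1:04d}",
                            subgenome=label)

            for i in range(n_genes + 1):
                spacer = anc_spacers[c][i].copy()
                _jc_branch(rng, spacer, ks_branch)
                emit(spacer)
                for rep in by_slot.get(i, ()):
                    s, e = emit(rep)
                    chrom_masks.append(MaskInterval(chrom, s, e, "repeat"))
                if i == n_genes:
                    break
                gene_id = f"{chrom}g{i + 1:04d}"
                if deleted[i]:
                    truth.deleted_genes.setdefault(label, []).append(gene_id)
                    continue
                cds_arr = _diverge_cds(rng, anc_genes[c][i], ks_branch, config.omega)
                g = emit_gene(gene_id, i, cds_arr)
                chrom_genes.append(g)
                retained[label][(c, i)] = gene_id
                if tandems[i] > 0:
                    array_ids = [gene_id]
                    for t in range(int(tandems[i])):
                        emit(_random_arr(rng, config.tandem_spacer))
                        tid = f"{gene_id}t{t + 1}"
                        tg = emit_gene(tid, i, cds_arr.copy())
                        chrom_genes.append(tg)
                        array_ids.append(tid)
                    truth.tandem_arrays.append(array_ids)

            genome.chromosomes[chrom] = "".join(parts)
            genome.genes.extend(chrom_genes)
            genome.masks.extend(chrom_masks)
            truth.subgenome_of[chrom] = label
            truth.deleted_genes.setdefault(label, [])

    for c in range(n_chrom):
        truth.homoeolog_pairs.append((f"A{c + 1:02d}", f"D{c + 1:02d}"))
        for i in range(n_genes):
            a = retained["A"].get((c, i))
            d = retained["D"].get((c, i))
            if a is not None and d is not None:
                truth.syntelog_pairs.append((a, d, config.subgenome_divergence_ks))
    return genome, truth


# --------------------------------------------------------------- B chromosome
def simulate_b_chromosome(genome: AnnotatedGenome, config: SimulationConfig,
                          truth: GroundTruth | None = None,
                          ) -> tuple[AnnotatedGenome, GroundTruth]:
    """Append a B chromosome mosaicked from 300-bp main-chromosome fragments.

    ``b_source_fraction`` of the B length (in whole ``b_fragment``-bp units) is
    copied from recorded main-chromosome coordinates outside repeat masks with
    per-base substitution noise ``b_noise``; the remainder is filled with noisy
    copies of a B-specific repeat consensus.
    """
    if not genome.chromosomes:
        raise ValueError("genome has no main chromosomes")
    rng = np.random.default_rng([config.seed, 2])
    truth = truth if truth is not None else GroundTruth()

    frag = config.b_fragment
    n_units = config.b_length // frag
    n_source = int(round(config.b_source_fraction * n_units))
    source_units = set(rng.choice(n_units, size=n_source, replace=False).tolist())

    chroms = sorted(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    weights = np.maximum(lengths - frag, 0)
    if weights.sum() == 0:
        raise ValueError(f"no main chromosome longer than {frag} bp")
    weights = weights / weights.sum()
    masks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in genome.masks:
        masks_by_chrom.setdefault(m.chrom, []).append((m.start, m.end))

    def overlaps_mask(chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in masks_by_chrom.get(chrom, ()))

    b_repeat = _random_arr(rng, frag)
    parts: list[str] = []
    for u in range(n_units):
        if u in source_units:
            for _ in range(200):
                ci = int(rng.choice(len(chroms), p=weights))
                chrom = chroms[ci]
                start = int(rng.integers(0, len(genome.chromosomes[chrom]) - frag + 1))
                if not overlaps_mask(chrom, start, start + frag):
                    break
            else:
                raise RuntimeError("could not place B source fragment outside masks")
            piece = _seq_to_arr(genome.chromosomes[chrom][start:start + frag])
            truth.b_source_segments.append((u * frag, (u + 1) * frag,
                                            chrom, start, start + frag))
        else:
            piece = b_repeat.copy()
        if config.b_noise > 0:
            hit = np.flatnonzero(rng.random(frag) < config.b_noise)
            if hit.size:
                piece[hit] = (piece[hit] + rng.integers(1, 4, size=hit.size)) % 4
        parts.append(_arr_to_seq(piece))

    b_name = "B01"
    out = AnnotatedGenome(chromosomes=dict(genome.chromosomes),
                          genes=list(genome.genes), masks=list(genome.masks))
    out.chromosomes[b_name] = "".join(parts)
    truth.b_chromosome = b_name
    truth.subgenome_of[b_name] = "B"
    truth.b_copies = config.b_copies
    return out, truth


# -------------------------------------------------------------- observations
def simulate_observations(genome: AnnotatedGenome, config: SimulationConfig,
                          truth: GroundTruth | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate allele depths at heterozygous CDS sites and windowed coverage.

    Heterozygous sites carry a single divergent copy, so the true alternate
    allele fraction is 1/2 for an allotetraploid (two subgenome-resolved
    copies) and 1/3 for an allohexaploid.  Total depth is Poisson
    (``mean_depth``); alternate depth is Binomial(total, fraction).  Windowed
    depth scales with local copy number: repeat windows are inflated by
    collapsed multi-mapping, one artifact region by ``artifact_fold``, and B
    windows by ``b_copies`` relative to the two-copy baseline of the main
    chromosomes.
    """
    rng = np.random.default_rng([config.seed, 3])
    truth = truth if truth is not None else GroundTruth()
    truth.ploidy = config.ploidy
    frac = 1.0 / (config.ploidy / 2.0)

    # Each possible single-base change is heterozygous independently at rate
    # heterozygosity_syn/3 if synonymous, heterozygosity_nonsyn/3 otherwise
    # (missense and nonsense), classified by the genetic code.  Summed over the
    # three alternatives per site this yields expected synonymous variant
    # counts of heterozygosity_syn times the NG86 synonymous site count, so
    # the generative pi values match the estimator's denominators exactly.
    rows: list[tuple] = []
    class_cache: dict[str, np.ndarray] = {}
    names = {1: "synonymous", 2: "missense", 3: "nonsense"}
    for g in sorted(genome.genes, key=lambda g: (g.chrom, g.start)):
        if g.subgenome not in ("A", "D"):
            continue
        cds = _seq_to_arr(g.cds)
        classes = np.zeros((cds.size, 4), dtype=np.int8)
        for ci in range(0, cds.size, 3):
            codon = g.cds[ci:ci + 3]
            tab = class_cache.get(codon)
            if tab is None:
                tab = _codon_change_classes(codon)
                class_cache[codon] = tab
            classes[ci:ci + 3] = tab
        rates = np.zeros_like(classes, dtype=float)
        rates[classes == 1] = config.heterozygosity_syn / 3.0
        rates[classes >= 2] = config.heterozygosity_nonsyn / 3.0
        hets = np.argwhere(rng.random(classes.shape) < rates)
        seen_pos: set[int] = set()
        for cds_i, alt_code in hets:
            cds_i, alt_code = int(cds_i), int(alt_code)
            if cds_i in seen_pos:      # keep sites biallelic
                continue
            seen_pos.add(cds_i)
            consequence = names[int(classes[cds_i, alt_code])]
            if g.strand == "+":
                gpos = g.start + cds_i
                ref_b, alt_b = "ACGT"[int(cds[cds_i])], "ACGT"[alt_code]
            else:
                gpos = g.end - 1 - cds_i
                ref_b, alt_b = "TGCA"[int(cds[cds_i])], "TGCA"[alt_code]
            total = int(rng.poisson(config.mean_depth))
            alt_d = int(rng.binomial(total, frac)) if total else 0
            rows.append((g.chrom, gpos + 1, ref_b, alt_b,
                         total - alt_d, alt_d, consequence))

    allele = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                         "ref_depth", "alt_depth", "consequence"])
    allele = allele.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    truth.het_sites = allele[["chrom", "pos", "ref", "alt", "consequence"]].copy()
    truth.true_pi_syn = config.heterozygosity_syn * 4.0 * frac * (1.0 - frac)
    truth.true_pi_nonsyn = config.heterozygosity_nonsyn * 4.0 * frac * (1.0 - frac)
    allele = allele.drop(columns="consequence")

    # ---- windowed coverage
    win = config.coverage_window
    mask_bases: dict[str, np.ndarray] = {}
    for m in genome.masks:
        arr = mask_bases.setdefault(m.chrom, np.zeros(len(genome.chromosomes[m.chrom]), bool))
        arr[m.start:m.end] = True

    main = sorted(c for c in genome.chromosomes if c != truth.b_chromosome)
    artifact_chrom = main[0]
    a_len = min(config.artifact_length, len(genome.chromosomes[artifact_chrom]))
    a_start = (len(genome.chromosomes[artifact_chrom]) - a_len) // 2
    truth.artifact_regions = [(artifact_chrom, a_start, a_start + a_len)]

    cov_rows: list[tuple] = []
    for chrom in sorted(genome.chromosomes):
        seq_len = len(genome.chromosomes[chrom])
        starts = np.arange(0, seq_len, win)
        ends = np.minimum(starts + win, seq_len)
        mult = np.ones(starts.size)
        masked = mask_bases.get(chrom)
        if masked is not None:
            frac_masked = np.add.reduceat(masked.astype(float), starts) / (ends - starts)
            mult[frac_masked >= 0.5] = config.repeat_depth_fold
        if chrom == artifact_chrom:
            centers = (starts + ends) / 2
            mult[(centers >= a_start) & (centers < a_start + a_len)] = config.artifact_fold
        if chrom == truth.b_chromosome:
            mult[:] = config.b_copies / 2.0 + config.mismap_rate
        lam = config.mean_depth * mult * (ends - starts)
        depth = rng.poisson(lam) / (ends - starts)
        cov_rows.extend(zip([chrom] * starts.size, starts.tolist(), ends.tolist(),
                            depth.tolist()))
    coverage = pd.DataFrame(cov_rows, columns=["chrom", "win_start", "win_end", "depth"])
    return allele, coverage, truth
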