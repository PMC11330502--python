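# Methods

## Scope and model

allokit analyses the aftermath of an allopolyploidy event: a genome carrying
two diverged progenitor chromosome sets (subgenomes A and D), possibly a
supernumerary B chromosome, sequenced as one individual. Every estimator is
paired with a generative model in `allokit.simulate` so that parameter
recovery can be demonstrated end-to-end; the statistics are the same ones a
practitioner would run on a real assembly (FASTA + GFF3 + depth tables).

## Synthetic genomes

An ancestral gene order (`n_chromosome_pairs` chromosomes ×
`genes_per_chromosome` genes of `codons_per_gene` codons, separated by
`intergenic_length`-bp spacers) is duplicated into subgenomes A and D; each
branch receives half the configured divergence.

**Coding sequences and divergence calibration.** CDS are composed of an ATG
start followed by codons drawn from the four 4-fold-degenerate families
Ala (GCN), Val (GTN), Thr (ACN) and Pro (CCN). This composition is a
deliberate design choice: every third position is a full synonymous site
with all three alternatives synonymous, and every first/second position is
fully nonsynonymous, so

- third positions evolve as an *exact* Jukes–Cantor process with total
  divergence `subgenome_divergence_ks` (transition applied per branch;
  JC transitions compose), giving an expected synonymous difference
  fraction of exactly ¾(1 − e^(−4Ks/3));
- first/second positions evolve at `omega × Ks`, so Ka/Ks recovers ω;
- no single-base change can create a stop codon (stops require T at
  position 1 with A/G at position 2; these families have G/A/C first bases
  and C/T second bases), keeping every CDS translatable. The rare stop
  created by a double hit within one codon is reverted at the second
  position.

Under a full-codon-table mutational process the NG86 estimator is biased at
2-fold degenerate sites, so the tight divergence-calibration property
(empirical synonymous difference fraction within 3 standard errors of the
JC expectation over ≥ 1,000 pairs) would not hold; the restricted codon
families make the calibration exact rather than approximate. The effect
annotator is nevertheless tested over all 64 codons × 9 single-base changes
against the genetic code, independent of the generator.

**Loss, tandems, repeats.** Each subgenome deletes ancestral genes
independently (Bernoulli `loss_fraction_A` / `loss_fraction_D`; defaults
0.15/0.10 produce the directional bias the fractionation stage must
detect). Retained genes gain Poisson(`tandem_rate`) adjacent tandem copies.
Each subgenome carries a private 500-bp repeat consensus inserted
intergenically at `repeats_per_chromosome` copies, with cross-subgenome
contamination at `1/repeat_family_fold` of that rate; copies are exact by
default (`repeat_divergence = 0`) so the planted count fold is
deterministic. Gene strands alternate deterministically. Intergenic
sequence diverges neutrally at the synonymous rate.

**B chromosome.** The B is a concatenation of `b_length/b_fragment` tiles
of `b_fragment` bp (default 300). A fraction `b_source_fraction` of tiles
(deterministic count, random placement) is copied from recorded
main-chromosome coordinates outside repeat masks — sampling inside
collapsed repeats would make origins untraceable by construction, and the
traceable portion of a real B is its gene-rich, low-copy content. The rest
are noisy copies of a B-private repeat consensus. All tiles receive
per-base substitution noise `b_noise` (default 2%).

**Observations.** Heterozygous sites carry one divergent copy among
`ploidy/2` homologous copies, so the true alternate-allele fraction is 1/2
(4x) or 1/3 (6x) — the single-divergent-copy configuration that produces
the 0.5 / 0.33 MAF peaks; total depth is Poisson(`mean_depth`), alternate
depth Binomial(total, fraction). Each possible single-base change in a CDS
is heterozygous independently with probability `heterozygosity_syn`/3 if
synonymous and `heterozygosity_nonsyn`/3 otherwise, classified by the
genetic code at planting time. Summed over the three alternatives per site,
the expected number of synonymous variants equals `heterozygosity_syn` ×
(NG86 synonymous site count), which makes the generative π values
(`heterozygosity × 4f(1−f)` with allele fraction f) exactly comparable to
the estimator's denominators. Windowed coverage multiplies the base depth
by 2-copy-relative dosage on the B (`b_copies/2`, plus a scalar
`mismap_rate`), by `repeat_depth_fold` on ≥ 50% repeat-masked windows
(collapsed multi-mapping), and by `artifact_fold` on one planted
artifact region.

All randomness flows from `numpy` generators seeded as
`default_rng([seed, stage])` (stage 1: genome, 2: B chromosome,
3: observations); identical configurations give byte-identical FASTA, GFF3,
BED and TSV outputs.

## Estimators and numerical choices

**Phasing.** Canonical k-mers (lexicographic minimum of the strand pair,
odd k so the canonical form is unique) are counted per chromosome with a
vectorised 2-bit encoding; windows containing non-ACGT bases are skipped.
Differential selection retains k-mers with total count ≥ `min_total`
(default 100) whose between-homoeolog fold is ≥ `min_fold` (default 2) in a
strict majority of pairs. The fold is max/min with the denominator floored
at one count: an additive pseudocount on both sides would make a planted
fold of exactly f unreachable at threshold f ((n+1)/(n/f+1) < f for all n),
rejecting precisely the boundary case the filter is meant to keep.
Chromosomes are clustered on the length-normalised differential matrix by
average-linkage hierarchical clustering with correlation distance, cut at
two groups; the homoeolog pairing is an input (from synteny or simulation
truth), and the clustering fails loudly if any pair lands in one cluster.
Labels are arbitrary up to a global A/D swap and anchored to the
lexicographically first chromosome. Homoeolog pairing is deliberately
separated from k-mer clustering as two concerns.

**Syntelogs and Ks.** Collinear chains of shared family identifiers are
extracted greedily (longest strictly-increasing chain by patience sorting,
forward or inverted, one-to-one within blocks, minimum block 5). Ks/Ka use
NG86 site counting (fraction of the three changes at each position that are
synonymous; changes to stops count as nonsynonymous) and per-codon
difference counting averaged over all mutational pathways that avoid stop
codons (all pathways if every one is blocked), followed by Jukes–Cantor
correction; p ≥ 3/4 is flagged undefined (nan). Pairs must be equal-length,
in-frame and stop-free. The Ks density is a fixed-bandwidth Gaussian KDE
(default 0.02 Ks units, grid step 0.005, reflected at zero) on Ks ≤ 5 —
values above 5 are synteny/annotation artifacts in real data and are
excluded globally; modes are local maxima at ≥ 10% of the peak density.
Dating uses T = Ks/(2r) with r from a calibration event (both lineages
accumulate substitutions, hence the 2).

**Fractionation.** Exclusive-loss counts are tested by a df-1
goodness-of-fit χ² against 50:50; a 2×2 retained/lost × subgenome
contingency variant (no continuity correction) is also provided because the
construction of such published tests is often ambiguous. Window profiles
use 100-gene windows with step 10 by default; the identity "occupancy-
weighted window mean = global retention" holds exactly when step = window
(tiling) and is asserted in that configuration.

**Tandems and enrichment.** Arrays merge same-family genes with ≤ `max_gap`
(default 10) intervening genes on one chromosome. Enrichment is the
hypergeometric upper tail per term; Bonferroni, Šidák, Holm and
Benjamini–Hochberg adjustments are all reported (via statsmodels). The GO
term map is a flat term → genes input; DAG propagation belongs upstream.

**B chromosome.** Copy ratio = mean unmasked-window depth on the B over the
same mean elsewhere; windows are masked when ≥ 50% of their bases fall
under repeat/artifact intervals, and additionally when their depth exceeds
3× the genome-wide median (median taken over repeat-mask-surviving windows,
in every lineage provided) — the signature of organelle insertions and
collapsed assembly errors. Interpretation: ratio ≈ B copies relative to the
2-copy baseline; ≤ 0.4 is read as "likely absent, residual mismapping".
Origin tracing seeds each 300-bp fragment with exact 15-mer matches (both
strands; seeds occurring > 100 times in the index are skipped as
unlocalisable repeats), groups seeds by diagonal, evaluates ungapped
identity on the best diagonals, and calls a fragment primary when its best
hit is unique with identity ≥ 0.8 covering ≥ 50%. A terminal remainder
≥ fragment/2 is kept as a fragment.

**Ploidy.** Sites are filtered to total depth in [20, 200] and minor-allele
depth > 7 (read strictly, i.e. ≥ 8; exposed as `--min-minor`, and applied
to the minor allele — the stricter reading). The folded MAF
min(ref, alt)/total is density-estimated with bandwidth 0.02 and reflection
at both 0 and 0.5 so a boundary peak is not shrunk inward; the unfolded
alternate fraction is reported alongside. Calls: primary mode in
[0.40, 0.50] → 4x-like, [0.30, 0.35] → 6x-like, else ambiguous. A 4x
individual is functionally diploid here because reads map uniquely to each
subgenome.

**Diversity.** π per class is single-individual heterozygosity — the study
design is one genome per accession — with each variant site contributing
2p(1−p)·n/(n−1), n = 2 allele draws and p the depth-estimated allele
fraction, divided by NG86 fractional site counts over all annotated CDS
(S + N = 3 × codons). Callable-site denominators therefore count sites, not
covered bases; this is what makes πN/πS comparable across ω. Frameshifts
and splice effects are not modelled (the generator emits SNVs only).

## Problem sizes

Default simulations are desk-scale by design: 12 chromosome pairs × 420
genes × 100 codons (≈ 5,000 ancestral genes, ≈ 6 Mb of sequence), a 120-kb
B chromosome (400 fragments), and recovery experiments of 20 seeds per
condition. These sizes keep the full test suite and the acceptance script
in the minutes range while leaving binomial/Poisson sampling errors well
inside the stated tolerances (e.g. the origin-fraction standard error at
400 fragments is ≈ 0.02 against a ±0.03 band, and the deterministic
source-tile count removes the dominant binomial term).

## What passing tests do and do not show

The generator reproduces the *statistical structure* the estimators assume:
planted divergence, biased loss, repeat enrichment folds, dosage-scaled
coverage, binomial allele depths. It does not emulate read-level error
profiles, mapping ambiguity beyond a scalar mismapping rate, indels,
recombination, segmental duplications, or assembly artifacts beyond one
planted high-depth region. Recovery on simulations therefore validates the
estimators' correctness and calibration, not their robustness to every
failure mode of real sequencing data. Printed-value checks (the πN/πS
table, the B-fragment percentage, the loss-count χ²) validate arithmetic
conventions — rounding, denominators, closed forms — against an external
anchor at printed precision.

## Known limitations

- NG86 with equal-pathway averaging is the minimal standard estimator;
  maximum-likelihood codon models (YN00/codeml-style) are out of scope.
- Syntelog chaining is a greedy longest-chain heuristic adequate for
  near-collinear subgenomes, not a general WGD-aware chainer.
- The GOF χ² on exclusive-loss counts assumes independent losses; linked
  losses (block deletions) would overdisperse it.
- The origin tracer's ungapped extension understates identity across
  indels; with SNV-only simulations this is exact, on real data it lower-
  bounds the sourced fraction.
- One diagnostic plot hook is deliberately absent: density/profile tables
  are emitted as TSV for external plotting.
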