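"""Generator correctness: determinism, calibration, conservation, truth."""
import numpy as np
import pytest

from allokit._codons import validate_cds
from allokit.genome import revcomp
from allokit.simulate import (SimulationConfig, simulate_allopolyploid,
                              simulate_b_chromosome, simulate_observations)
from allokit.synteny import compute_ks

from oracles import oracle_ng86


def test_config_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        SimulationConfig(loss_fraction_A=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(subgenome_divergence_ks=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(subgenome_divergence_ks=5.0)  # JC saturation zone
    with pytest.raises(ValueError):
        SimulationConfig(ploidy=5)
    with pytest.raises(ValueError):
        SimulationConfig(b_source_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(mean_depth=0)


def test_same_seed_gives_byte_identical_serializations(tmp_path, small_cfg):
    outs = []
    for run in ("x", "y"):
        genome, truth = simulate_allopolyploid(small_cfg)
        genome, truth = simulate_b_chromosome(genome, small_cfg, truth)
        d = tmp_path / run
        d.mkdir()
        genome.write_fasta(d / "g.fasta")
        genome.write_gff3(d / "g.gff3")
        genome.write_masks_bed(d / "m.bed")
        outs.append(d)
    for name in ("g.fasta", "g.gff3", "m.bed"):
        assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()


def test_genome_is_internally_consistent(small_sim):
    genome, truth, _, _ = small_sim
    genome.validate()
    truth.validate_against(genome)
    for g in genome.genes:
        if g.subgenome in "AD":
            validate_cds(g.cds, g.gene_id)


def test_zero_divergence_gives_identical_homoeologs():
    cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=30,
                           codons_per_gene=40, subgenome_divergence_ks=0.0,
                           loss_fraction_A=0.0, loss_fraction_D=0.0,
                           tandem_rate=0.0, seed=1)
    genome, truth = simulate_allopolyploid(cfg)
    index = genome.gene_index()
    for a, d, _ in truth.syntelog_pairs:
        assert index[a].cds == index[d].cds
        assert compute_ks(index[a].cds, index[d].cds).ks == 0.0


def test_gene_count_conservation_and_loss_asymmetry():
    cfg = SimulationConfig(n_chromosome_pairs=4, genes_per_chromosome=150,
                           codons_per_gene=30, loss_fraction_A=0.15,
                           loss_fraction_D=0.10, seed=2)
    genome, truth = simulate_allopolyploid(cfg)
    n_anc = cfg.n_chromosome_pairs * cfg.genes_per_chromosome
    for label in "AD":
        retained = sum(1 for g in genome.genes
                       if g.subgenome == label and "t" not in g.gene_id.split("g")[1])
        assert retained + len(truth.deleted_genes[label]) == n_anc
    # the higher-loss subgenome retains fewer genes
    assert len(truth.deleted_genes["A"]) > len(truth.deleted_genes["D"])


def test_synonymous_divergence_matches_jc_expectation():
    """Mean synonymous difference fraction over >=1000 homoeolog pairs sits
    within 3 standard errors of 3/4(1-exp(-4 Ks/3))."""
    cfg = SimulationConfig(n_chromosome_pairs=2, genes_per_chromosome=500,
                           codons_per_gene=120, loss_fraction_A=0.0,
                           loss_fraction_D=0.0, tandem_rate=0.0, seed=3)
    genome, truth = simulate_allopolyploid(cfg)
    index = genome.gene_index()
    assert len(truth.syntelog_pairs) >= 1000
    ps_list, weights = [], []
    for a, d, _ in truth.syntelog_pairs:
        res = compute_ks(index[a].cds, index[d].cds)
        ps_list.append(res.ps)
        weights.append(res.syn_sites)
    ps = np.average(ps_list, weights=weights)
    expected = 0.75 * (1 - np.exp(-4 * cfg.subgenome_divergence_ks / 3))
    n_sites = float(np.sum(weights))
    se = np.sqrt(expected * (1 - expected) / n_sites)
    assert abs(ps - expected) < 3 * se


def test_ng86_matches_oracle_on_simulated_pair(small_sim):
    genome, truth, _, _ = small_sim
    index = genome.gene_index()
    a, d, _ = truth.syntelog_pairs[0]
    res = compute_ks(index[a].cds, index[d].cds)
    ps, pn, S, N = oracle_ng86(index[a].cds, index[d].cds)
    assert res.ps == pytest.approx(ps, abs=1e-12)
    assert res.pn == pytest.approx(pn, abs=1e-12)


def test_b_chromosome_source_and_noise_free_tiles():
    cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=80,
                           codons_per_gene=60, b_source_fraction=1.0,
                           b_noise=0.0, b_length=30_000, seed=4)
    genome, truth = simulate_allopolyploid(cfg)
    genome_b, truth = simulate_b_chromosome(genome, cfg, truth)
    b = genome_b.chromosomes[truth.b_chromosome]
    assert len(truth.b_source_segments) == len(b) // cfg.b_fragment
    joined = {c: genome.chromosomes[c] for c in genome.chromosomes}
    for b0, b1, chrom, s, e in truth.b_source_segments[:20]:
        tile = b[b0:b1]
        assert tile == joined[chrom][s:e] or tile == revcomp(joined[chrom][s:e])


def test_b_source_fraction_zero_gives_no_source_segments():
    cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=40,
                           codons_per_gene=40, b_source_fraction=0.0,
                           b_length=15_000, seed=5)
    genome, truth = simulate_allopolyploid(cfg)
    _, truth = simulate_b_chromosome(genome, cfg, truth)
    assert truth.b_source_segments == []


@pytest.mark.parametrize("ploidy,expected", [(4, 0.5), (6, 1 / 3)])
def test_alt_fraction_converges_to_copy_fraction(ploidy, expected):
    """Mean alternate fraction at het sites approaches 1/2 (4x) or 1/3 (6x)."""
    cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=200,
                           codons_per_gene=100, ploidy=ploidy, mean_depth=200,
                           heterozygosity_syn=0.02, heterozygosity_nonsyn=0.01,
                           seed=6)
    genome, truth = simulate_allopolyploid(cfg)
    allele, _, _ = simulate_observations(genome, cfg, truth)
    frac = allele["alt_depth"] / (allele["ref_depth"] + allele["alt_depth"])
    assert abs(frac.mean() - expected) < 0.02


def test_absent_b_has_only_mismapping_depth(small_cfg):
    cfg = small_cfg.with_(b_copies=0)
    genome, truth = simulate_allopolyploid(cfg)
    genome, truth = simulate_b_chromosome(genome, cfg, truth)
    _, coverage, _ = simulate_observations(genome, cfg, truth)
    on_b = coverage[coverage["chrom"] == truth.b_chromosome]["depth"]
    assert on_b.mean() < 3 * cfg.mismap_rate * cfg.mean_depth
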