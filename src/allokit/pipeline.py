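"""End-to-end pipeline: simulate -> phase -> Ks -> fractionation -> tandem ->
B chromosome -> ploidy -> diversity, with a collated JSON + Markdown report.

Every stage is a pure function of (inputs, parameters, seed); the report
records the configuration hash and seed so a rerun reproduces it bit for bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bchrom, diversity, fractionation, phase, ploidy, synteny, tandem
from .genome import write_allele_depths, write_coverage
from .simulate import (SimulationConfig, simulate_allopolyploid,
                       simulate_b_chromosome, simulate_observations)

log = logging.getLogger("allokit")

_STAGES = ("simulate", "phase", "ks", "fractionation", "tandem",
           "bchrom", "ploidy", "diversity")


@dataclass
class PipelineConfig:
    outdir: str = "allokit_out"
    seed: int = 42
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    simulate: dict = field(default_factory=dict)       # SimulationConfig overrides
    phase_params: dict = field(default_factory=lambda: {
        "k": 13, "min_total": 100, "min_fold": 2.0})
    ks_params: dict = field(default_factory=lambda: {
        "min_block": 5, "bandwidth": 0.02, "ks_filter_max": 5.0,
        "calibration_ks": 0.45, "calibration_t": 70e6})
    fractionation_params: dict = field(default_factory=lambda: {
        "window": 100, "step": 10})
    tandem_params: dict = field(default_factory=lambda: {"max_gap": 10})
    bchrom_params: dict = field(default_factory=lambda: {
        "window": 1000, "fragment": 300, "min_identity": 0.8, "min_cov": 0.5})
    ploidy_params: dict = field(default_factory=lambda: {
        "min_total": 20, "max_total": 200, "min_minor": 8})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output path is incidental)."""
        payload = asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stages": {}}
    t_all = time.time()

    def stage(name):
        enabled = name in config.stages
        if enabled:
            log.info("stage %s ...", name)
        return enabled

    sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulate})
    t0 = time.time()
    genome, truth = simulate_allopolyploid(sim_cfg)
    genome, truth = simulate_b_chromosome(genome, sim_cfg, truth)
    allele, coverage, truth = simulate_observations(genome, sim_cfg, truth)
    if stage("simulate"):
        genome.write_fasta(outdir / "genome.fasta")
        genome.write_gff3(outdir / "genes.gff3")
        genome.write_masks_bed(outdir / "masks.bed")
        write_allele_depths(allele, outdir / "allele_depths.tsv")
        write_coverage(coverage, outdir / "coverage.tsv")
        truth.to_json(outdir / "truth.json")
        report["stages"]["simulate"] = {
            "n_chromosomes": len(genome.chromosomes),
            "n_genes": len(genome.genes),
            "n_het_sites": int(len(allele)),
            "runtime_s": round(time.time() - t0, 2)}

    main_genome = type(genome)(
        chromosomes={c: s for c, s in genome.chromosomes.items()
                     if c != truth.b_chromosome},
        genes=list(genome.genes), masks=list(genome.masks))

    if stage("phase"):
        t0 = time.time()
        p = config.phase_params
        matrix = phase.count_kmers(main_genome, k=p["k"])
        diff = phase.select_differential_kmers(
            matrix, truth.homoeolog_pairs, min_total=p["min_total"],
            min_fold=p["min_fold"])
        assignment = phase.assign_subgenomes(diff, truth.homoeolog_pairs)
        assignment.to_frame().to_csv(outdir / "subgenomes.tsv", sep="\t", index=False)
        report["stages"]["phase"] = {
            "n_differential_kmers": int(sum(c.size for c in diff.codes.values())),
            "labels": assignment.labels,
            "runtime_s": round(time.time() - t0, 2)}

    pairs = None
    if stage("ks"):
        t0 = time.time()
        p = config.ks_params
        pairs = []
        for a_chrom, d_chrom in truth.homoeolog_pairs:
            pairs.extend(synteny.find_syntelogs(
                genome.genes_on(a_chrom), genome.genes_on(d_chrom),
                min_block=p["min_block"]))
        synteny.attach_ks(pairs)
        dist = synteny.ks_modes([q.ks for q in pairs], bandwidth=p["bandwidth"],
                                ks_filter_max=p["ks_filter_max"])
        clock = synteny.calibrate(p["calibration_ks"], p["calibration_t"])
        dated = {f"{m:.3f}": clock.date(m) for m in dist.modes}
        report["stages"]["ks"] = {
            "n_pairs": len(pairs), "modes": dist.modes,
            "primary_mode": dist.primary_mode,
            "dated_modes_years": dated,
            "runtime_s": round(time.time() - t0, 2)}

    if stage("fractionation"):
        t0 = time.time()
        p = config.fractionation_params
        anc_of = _ancestor_maps(truth)
        anc_by_chrom, all_anc = _ancestor_order(truth)
        deleted_a = {anc_of[g] for g in truth.deleted_genes.get("A", [])}
        deleted_d = {anc_of[g] for g in truth.deleted_genes.get("D", [])}
        rt = fractionation.build_retention(
            all_anc, set(all_anc) - deleted_a, set(all_anc) - deleted_d)
        test = fractionation.loss_bias_test(rt.a_only, rt.d_only)
        profile = fractionation.retention_windows(
            rt, anc_by_chrom, window=min(p["window"], min(map(len, anc_by_chrom.values()))),
            step=p["step"])
        profile.to_csv(outdir / "retention_profile.tsv", sep="\t", index=False)
        report["stages"]["fractionation"] = {
            "both": rt.both, "a_only": rt.a_only, "d_only": rt.d_only,
            "neither": rt.neither, "chi2": test.statistic, "p": test.p_value,
            "runtime_s": round(time.time() - t0, 2)}

    if stage("tandem"):
        t0 = time.time()
        p = config.tandem_params
        ordered = sorted((g for g in genome.genes if g.subgenome in "AD"),
                         key=lambda g: (g.chrom, g.start))
        arrays = tandem.find_tandem_arrays(ordered, max_gap=p["max_gap"])
        study = tandem.tandem_gene_ids(arrays)
        population = {g.gene_id for g in ordered}
        term_map = _synthetic_term_map(population, config.seed)
        enrich = tandem.go_enrichment(study, population, term_map)
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["tandem"] = {
            "n_arrays": len(arrays), "n_tandem_genes": len(study),
            "n_terms_tested": int(len(enrich)),
            "n_terms_significant": int((enrich["p_bonferroni"] < 0.05).sum()),
            "runtime_s": round(time.time() - t0, 2)}

    if stage("bchrom"):
        t0 = time.time()
        p = config.bchrom_params
        track = bchrom.window_coverage(coverage, genome.masks, window=p["window"])
        est = bchrom.b_copy_ratio(track, truth.b_chromosome)
        trace = bchrom.trace_origins(
            genome.chromosomes[truth.b_chromosome], main_genome,
            fragment=p["fragment"], min_identity=p["min_identity"],
            min_cov=p["min_cov"])
        trace.fragments.to_csv(outdir / "b_fragments.tsv", sep="\t", index=False)
        report["stages"]["bchrom"] = {
            "coverage_ratio": est.ratio, "interpretation": est.interpretation,
            "n_fragments": trace.n_fragments, "n_primary": trace.n_primary,
            "primary_percent": trace.percent,
            "runtime_s": round(time.time() - t0, 2)}

    if stage("ploidy"):
        t0 = time.time()
        p = config.ploidy_params
        kept, removed = ploidy.filter_sites(
            allele, min_total=p["min_total"], max_total=p["max_total"],
            min_minor=p["min_minor"])
        profile = ploidy.maf_density(kept)
        report["stages"]["ploidy"] = {
            "n_sites": int(len(kept)), "removed": removed,
            "maf_mode": profile.mode, "call": profile.call,
            "runtime_s": round(time.time() - t0, 2)}

    if stage("diversity"):
        t0 = time.time()
        annotated = diversity.annotate_effects(allele, genome)
        summary = diversity.pi_by_class(annotated, genome)
        report["stages"]["diversity"] = {
            "pi_nonsyn": summary.pi_nonsyn, "pi_syn": summary.pi_syn,
            "ratio": summary.ratio,
            "n_syn_variants": summary.n_syn_variants,
            "n_nonsyn_variants": summary.n_nonsyn_variants,
            "runtime_s": round(time.time() - t0, 2)}

    report["total_runtime_s"] = round(time.time() - t_all, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                   default=_jsonable))
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _ancestor_maps(truth) -> dict[str, str]:
    """Map subgenome gene id (e.g. A03g0005) to an ancestor id (c03g0005)."""
    out = {}
    for label, ids in truth.deleted_genes.items():
        for gid in ids:
            out[gid] = "c" + gid[1:]
    for a, d, _ in truth.syntelog_pairs:
        out[a] = "c" + a[1:]
        out[d] = "c" + d[1:]
    return out


def _ancestor_order(truth) -> tuple[dict[str, list[str]], list[str]]:
    by_chrom: dict[str, list[str]] = {}
    seen = set()
    ids = sorted(set(_ancestor_maps(truth).values()))
    for gid in ids:
        chrom = gid.split("g")[0]
        if gid not in seen:
            by_chrom.setdefault(chrom, []).append(gid)
            seen.add(gid)
    return by_chrom, [g for c in sorted(by_chrom) for g in by_chrom[c]]


def _synthetic_term_map(population: set[str], seed: int,
                        n_terms: int = 40) -> dict[str, set[str]]:
    """Random flat term->genes map standing in for an upstream GO annotation."""
    rng = np.random.default_rng([seed, 7])
    genes = sorted(population)
    term_map: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(10, max(11, len(genes) // 10)))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        term_map[f"TERM:{t:04d}"] = {genes[i] for i in members}
    return term_map


def _markdown_report(report: dict) -> str:
    lines = ["# allokit pipeline report", "",
             f"- config hash: `{report['config_hash']}`",
             f"- seed: {report['seed']}", ""]
    for name, info in report["stages"].items():
        lines.append(f"## {name}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    lines.append(f"total runtime: {report['total_runtime_s']} s")
    return "\n".join(lines) + "\n"
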