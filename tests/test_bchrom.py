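"""Coverage windows, B dosage ratio and fragment origin tracing."""
import numpy as np
import pandas as pd
import pytest

from allokit.bchrom import (CoverageTrack, b_copy_ratio, trace_origins,
                            window_coverage)
from allokit.genome import AnnotatedGenome, MaskInterval
from allokit.simulate import (SimulationConfig, simulate_allopolyploid,
                              simulate_b_chromosome, simulate_observations)


def _depth_df(chrom_lengths, depth=30.0, window=1000):
    rows = []
    for chrom, length in chrom_lengths.items():
        for s in range(0, length, window):
            rows.append((chrom, s, min(s + window, length), depth))
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "depth"])


class TestWindowCoverage:
    def test_constant_depth_without_masks(self):
        df = _depth_df({"c1": 5000})
        track = window_coverage(df, [], window=1000)
        assert (track.windows["depth"] == 30.0).all()
        assert (track.windows["mask"] == "").all()

    def test_majority_repeat_window_is_flagged(self):
        df = _depth_df({"c1": 3000})
        masks = [MaskInterval("c1", 1000, 1600, "repeat")]
        track = window_coverage(df, masks, window=1000)
        flagged = track.windows.set_index("win_start")["mask"]
        assert flagged[1000] == "repeat"
        assert flagged[0] == "" and flagged[2000] == ""

    def test_terminal_short_window_kept(self):
        df = _depth_df({"c1": 2500})
        track = window_coverage(df, [], window=1000)
        assert track.windows["win_end"].max() == 2500

    def test_cross_lineage_spike_flagged_artifact(self):
        df = _depth_df({"c1": 10_000})
        for frame in (df,):
            frame.loc[frame["win_start"] == 3000, "depth"] = 400.0
        other = df.copy()
        track = window_coverage(df, [], window=1000,
                                artifact_tracks={"lineage2": other})
        flagged = track.windows.set_index("win_start")["mask"]
        assert flagged[3000] == "artifact"
        assert (flagged.drop(3000) == "").all()

    def test_planted_artifact_region_recovered_from_simulation(self):
        cfg = SimulationConfig(n_chromosome_pairs=2, genes_per_chromosome=100,
                               codons_per_gene=60, seed=50)
        genome, truth = simulate_allopolyploid(cfg)
        genome, truth = simulate_b_chromosome(genome, cfg, truth)
        _, coverage, truth = simulate_observations(genome, cfg, truth)
        track = window_coverage(coverage, genome.masks, window=1000)
        chrom, a0, a1 = truth.artifact_regions[0]
        win = track.windows
        inside = win[(win["chrom"] == chrom) & (win["win_start"] >= a0)
                     & (win["win_end"] <= a1)]
        # every spiked window is excluded from the estimate; repeat masking
        # takes precedence where the spike overlaps annotated repeats
        assert (inside["mask"] != "").all()
        assert (inside["mask"] == "artifact").any()


class TestCopyRatio:
    def _track(self, b_depth, rest_depth, mask_b=None):
        rows = []
        for i in range(20):
            rows.append(("B01", i * 1000, (i + 1) * 1000, b_depth,
                         mask_b[i] if mask_b else ""))
            rows.append(("c1", i * 1000, (i + 1) * 1000, rest_depth, ""))
        return CoverageTrack(pd.DataFrame(
            rows, columns=["chrom", "win_start", "win_end", "depth", "mask"]))

    def test_ratio_is_linear_in_b_depth(self):
        r1 = b_copy_ratio(self._track(30, 30), "B01").ratio
        r3 = b_copy_ratio(self._track(90, 30), "B01").ratio
        assert r3 == pytest.approx(3 * r1)

    def test_masked_windows_do_not_affect_the_estimate(self):
        base = b_copy_ratio(self._track(30, 30), "B01").ratio
        mask_b = ["repeat" if i < 5 else "" for i in range(20)]
        poisoned = self._track(30, 30, mask_b)
        poisoned.windows.loc[(poisoned.windows["mask"] == "repeat"), "depth"] = 9999
        assert b_copy_ratio(poisoned, "B01").ratio == pytest.approx(base)

    def test_zero_b_depth_gives_zero_ratio(self):
        assert b_copy_ratio(self._track(0.0, 30), "B01").ratio == 0.0

    def test_fully_masked_side_rejected(self):
        track = self._track(30, 30, ["repeat"] * 20)
        with pytest.raises(ValueError):
            b_copy_ratio(track, "B01")


class TestTraceOrigins:
    def test_verbatim_b_has_unit_primary_fraction(self):
        cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=100,
                               codons_per_gene=60, b_source_fraction=1.0,
                               b_noise=0.0, b_length=30_000, seed=51)
        genome, truth = simulate_allopolyploid(cfg)
        genome_b, truth = simulate_b_chromosome(genome, cfg, truth)
        main = AnnotatedGenome(
            chromosomes={c: s for c, s in genome_b.chromosomes.items()
                         if c != truth.b_chromosome},
            masks=genome_b.masks)
        trace = trace_origins(genome_b.chromosomes[truth.b_chromosome], main)
        assert trace.fraction == 1.0

    def test_pure_filler_b_has_near_zero_primary_fraction(self):
        cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=100,
                               codons_per_gene=60, b_source_fraction=0.0,
                               b_length=30_000, seed=52)
        genome, truth = simulate_allopolyploid(cfg)
        genome_b, truth = simulate_b_chromosome(genome, cfg, truth)
        main = AnnotatedGenome(
            chromosomes={c: s for c, s in genome_b.chromosomes.items()
                         if c != truth.b_chromosome})
        trace = trace_origins(genome_b.chromosomes[truth.b_chromosome], main)
        assert trace.fraction <= 0.02

    def test_tiling_conserves_b_length(self):
        cfg = SimulationConfig(n_chromosome_pairs=1, genes_per_chromosome=60,
                               codons_per_gene=40, b_length=20_000, seed=53)
        genome, truth = simulate_allopolyploid(cfg)
        genome_b, truth = simulate_b_chromosome(genome, cfg, truth)
        b_seq = genome_b.chromosomes[truth.b_chromosome]
        main = AnnotatedGenome(
            chromosomes={c: s for c, s in genome_b.chromosomes.items()
                         if c != truth.b_chromosome})
        trace = trace_origins(b_seq, main, fragment=300)
        covered = (trace.fragments["b_end"] - trace.fragments["b_start"]).sum()
        assert len(b_seq) - covered < 150       # discarded remainder < frag/2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            trace_origins("A" * 1000, AnnotatedGenome(chromosomes={}), fragment=300)
        with pytest.raises(ValueError):
            trace_origins("A" * 1000,
                          AnnotatedGenome(chromosomes={"c": "ACGT" * 300}),
                          fragment=20)

    def test_printed_totals_reproduce_printed_percentage(self):
        from allokit.bchrom import FragmentTrace
        import pandas as pd
        trace = FragmentTrace(fragments=pd.DataFrame(), n_fragments=70_085,
                              n_primary=17_013)
        assert trace.percent == 24.27
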