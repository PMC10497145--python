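"""Generator contracts: waveforms, count noise model, planted promoters."""

import numpy as np
import pandas as pd
import pytest

import dielseason as ds
from dielseason import simulate as sim
from dielseason.simulate import MotifPlacement

HOURS = {"SD": 8, "EQ": 12, "LD": 16}
ZT = np.array([0, 4, 8, 12, 16, 20], dtype=float)


class TestMeanTrace:
    def test_constant_archetype_is_flat(self):
        a = sim.archetype("constant")
        for pp, h in HOURS.items():
            assert sim.mean_trace(a, h, ZT, pp) == pytest.approx([200.0] * 6)

    def test_unknown_archetype_raises(self):
        with pytest.raises(ValueError, match="unknown archetype"):
            sim.archetype("not-a-pattern")

    def test_postdusk_gene_higher_in_sd_at_zt12(self):
        # dusk is ZT8 in short days (pulse already fired by ZT12) but ZT16
        # in long days (pulse not yet fired), so SD > LD at ZT12
        a = sim.archetype("11Oa-postdusk")
        assert sim.mean_trace(a, 8, 12.0, "SD") > sim.mean_trace(a, 16, 12.0, "LD")

    def test_clock_archetype_phase_shifts_with_daylength(self):
        # slope 0.5 h per hour of light: LD (16 h) peaks 4 h later than SD (8 h)
        a = sim.archetype("3N-clock-phase-delay")
        grid = np.arange(0, 24, 0.01)
        peak_sd = grid[np.argmax(sim.mean_trace(a, 8, grid, "SD"))]
        peak_ld = grid[np.argmax(sim.mean_trace(a, 16, grid, "LD"))]
        assert peak_ld - peak_sd == pytest.approx(4.0, abs=0.02)

    def test_time_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            sim.mean_trace(sim.archetype("constant"), 8, 24.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sim.ArchetypeSpec(name="bad", waveform_params={"dusk_amp": -1.0})


class TestSimulateCounts:
    def test_fixed_seed_reproducible(self):
        specs, _ = sim.make_gene_population({"3R": 5, "11L": 5}, seed=3)
        d = sim.DesignSpec(seed=7)
        exp1, _ = sim.simulate_counts(d, specs, dispersion=0.05)
        exp2, _ = sim.simulate_counts(d, specs, dispersion=0.05)
        assert exp1.counts.equals(exp2.counts)

    def test_poisson_limit_variance_equals_mean(self):
        d = sim.DesignSpec(seed=5, library_size_range=(1.0, 1.0))
        specs = [sim.archetype("constant")] * 400
        exp, _ = sim.simulate_counts(d, specs, dispersion=0.0)
        draws = exp.counts.to_numpy().ravel().astype(float)
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.05)

    def test_nb_variance_matches_dispersion(self, rng):
        # var = m + phi m^2 = 100 + 0.1 * 1e4 = 1100 at m=100
        d = sim.DesignSpec(seed=9, library_size_range=(1.0, 1.0))
        spec = sim.ArchetypeSpec(name="constant", baseline_mean=100.0)
        exp, _ = sim.simulate_counts(d, [spec] * 200, dispersion=0.1)
        draws = exp.counts.to_numpy().ravel().astype(float)
        assert draws.var() == pytest.approx(1100.0, rel=0.10)

    def test_spikeins_constant_and_flagged(self):
        specs, _ = sim.make_gene_population({"3R": 4}, seed=1)
        exp, truth = sim.simulate_counts(sim.DesignSpec(seed=1), specs,
                                         n_spikeins=3)
        assert exp.spikein.sum() == 3
        spike_truth = truth.genes[truth.genes.index.str.startswith("SPIKE")]
        assert (spike_truth["archetype"] == "constant").all()

    def test_true_dei_matches_sampled_trapezoid(self):
        # DEI of the noiseless trace sampled on the 4-h grid agrees with the
        # fine-grid truth integral to within trapezoid discretization error
        for name in ("3R", "11Oa-postdusk", "3N-clock-phase-delay"):
            a = sim.archetype(name)
            for pp, h in HOURS.items():
                sampled = ds.dei_trapezoid(sim.mean_trace(a, h, ZT, pp), ZT)
                fine = sim._true_dei(a, h, pp)
                assert sampled == pytest.approx(fine, rel=0.15)

    def test_archetype_separability_preset(self):
        names = sim.ARCHETYPE_NAMES
        traces = np.array([
            np.concatenate([sim.mean_trace(sim.archetype(n), h, ZT, pp)
                            for pp, h in HOURS.items()])
            for n in names])
        corr = np.corrcoef(traces)
        off = corr[~np.eye(len(names), dtype=bool)]
        assert off.mean() < 0.5
        # genes of one archetype differ only by positive scaling -> r = 1
        specs, _ = sim.make_gene_population({"3R": 2}, seed=0, amp_jitter=0.0,
                                            gain_jitter=0.0)
        t1 = np.concatenate([sim.mean_trace(specs[0], h, ZT, pp)
                             for pp, h in HOURS.items()])
        t2 = np.concatenate([sim.mean_trace(specs[1], h, ZT, pp)
                             for pp, h in HOURS.items()])
        assert np.corrcoef(t1, t2)[0, 1] > 0.9


class TestPlantPromoters:
    def test_plus_strand_consensus_at_offset(self, tmp_path):
        genes = ["GP001", "GP002"]
        genome = sim.plant_promoters(
            genes, {"GP001": [MotifPlacement("Gbox", -100, "+")]},
            {"Gbox": "CACGTG"}, seed=4)
        genome.write_fasta(tmp_path / "g.fa")
        genome.write_gff3(tmp_path / "g.gff3")
        proms = ds.extract_promoters(tmp_path / "g.fa", tmp_path / "g.gff3")
        seq = proms["GP001"].sequence
        # offset -100 from the TSS = promoter string index 1400
        assert seq[1400:1406] == "CACGTG"

    def test_minus_strand_revcomp_in_genome(self, tmp_path):
        genes = ["GM001", "GM002"]          # second gene is minus strand
        genome = sim.plant_promoters(
            genes, {"GM002": [MotifPlacement("m", -50, "+")]},
            {"m": "AAACCC"}, seed=5)
        row = genome.genes.loc["GM002"]
        assert row.strand == "-"
        chrom = genome.sequences[row.chrom]
        tss = row.end
        g0 = tss - (-50) - 6                 # 0-based genomic start
        assert chrom[g0:g0 + 6] == "GGGTTT"  # reverse complement on genome
        genome.write_fasta(tmp_path / "g.fa")
        genome.write_gff3(tmp_path / "g.gff3")
        proms = ds.extract_promoters(tmp_path / "g.fa", tmp_path / "g.gff3")
        assert proms["GM002"].sequence[1450:1456] == "AAACCC"

    def test_offset_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside promoter window"):
            sim.plant_promoters(["G1"],
                                {"G1": [MotifPlacement("m", 499, "+")]},
                                {"m": "ACGTAC"})

    def test_planted_enrichment_recovered_downstream(self, tmp_path):
        # 50/60 targets carry the motif vs 10/140 background: the
        # hypergeometric tail must be tiny
        rng = np.random.default_rng(6)
        genes = [f"G{i:04d}" for i in range(200)]
        targets = genes[:60]
        carriers = targets[:50] + list(rng.choice(genes[60:], 10, replace=False))
        pfm = np.full((4, 8), 0.01)
        consensus = "CACGTGGC"
        for i, b in enumerate(consensus):
            pfm["ACGT".index(b), i] = 0.97
        pfm /= pfm.sum(axis=0, keepdims=True)
        assign = {g: [MotifPlacement("M1", -200, "+")] for g in carriers}
        genome = sim.plant_promoters(genes, assign, {"M1": pfm}, seed=6)
        genome.write_fasta(tmp_path / "g.fa")
        genome.write_gff3(tmp_path / "g.gff3")
        proms = ds.extract_promoters(tmp_path / "g.fa", tmp_path / "g.gff3")
        pwm = ds.PositionWeightMatrix("M1", pfm)
        res = ds.motif_enrichment(targets, genes, proms, [pwm], 8.0)
        # PFM-drawn instances occasionally mutate below the threshold and a
        # couple of background promoters match by chance; the tail is still
        # decisively small
        assert res.loc["M1", "p"] < 1e-5
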