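"""The twin-supercoiled-domain generator: annotation, fields, sampling, fixtures."""
import numpy as np
import pytest
from scipy.stats import spearmanr

import torsionmap as tm
from torsionmap.synth import SyntheticTruth


def small_params(**kw):
    defaults = dict(n_chromosomes=1, chromosome_length=60_000, depth_scale=3000.0,
                    seed=11)
    defaults.update(kw)
    return tm.SimulationParams(**defaults)


def manual_truth(genes, length=100_000, **param_kw):
    params = tm.SimulationParams(n_chromosomes=1, chromosome_length=length,
                                 **param_kw)
    genome = tm.GenomeIndex(("chr1",), (length,), params.bin_width)
    return SyntheticTruth(params, genome, genes)


class TestAnnotationGeneration:
    def test_deterministic_given_seed(self):
        t1 = tm.make_genome_and_genes(small_params())
        t2 = tm.make_genome_and_genes(small_params())
        assert t1.genes == t2.genes
        assert t1.insulators == t2.insulators

    def test_all_plus_strands_yield_only_codirectional_pairs(self):
        truth = tm.make_genome_and_genes(small_params(strand_plus_probability=1.0))
        pairs = tm.classify_gene_pairs(truth.genes)
        assert pairs
        assert {p.configuration for p in pairs} == {"codirectional"}
        assert truth.divergent_pairs == []

    def test_orfs_do_not_overlap(self, default_sim):
        from torsionmap.annotation import genes_by_chrom
        truth, _ = default_sim
        for chrom, genes in genes_by_chrom(truth.genes).items():
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_mean_gene_length_matches_lognormal(self, default_sim):
        truth, _ = default_sim
        p = truth.params
        sizes = np.array([g.size for g in truth.genes])
        assert len(sizes) >= 500
        mu, sd = p.gene_length_log_mean, p.gene_length_log_sd
        expect = np.exp(mu + sd ** 2 / 2)
        se = expect * np.sqrt(np.exp(sd ** 2) - 1) / np.sqrt(len(sizes))
        assert abs(sizes.mean() - expect) < 3 * se

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            tm.make_genome_and_genes(small_params(chromosome_length=300))


class TestAccessibilityField:
    def test_no_modulation_gives_flat_baseline(self):
        truth = manual_truth([tm.Gene("chr1", 40_000, 42_000, "+", "g",
                                      expression=1.0)],
                             nfr_amplitude=0.0, nucleosome_amplitude=0.0)
        a = tm.accessibility_field(truth)
        assert np.allclose(a.values(), truth.params.accessibility_baseline)

    def test_gene_body_periodicity_near_repeat_length(self):
        truth = manual_truth([tm.Gene("chr1", 40_000, 48_000, "+", "g",
                                      expression=1.0)])
        a = tm.accessibility_field(truth)
        body = a["chr1"][4000:4800]
        period = tm.autocorrelation_period_bp(body, 10)
        assert abs(period - truth.params.nucleosome_repeat_bp) <= 10

    def test_minus_strand_pattern_mirrors_plus(self):
        plus = manual_truth([tm.Gene("chr1", 40_000, 44_000, "+", "g", expression=1.0)])
        minus = manual_truth([tm.Gene("chr1", 56_000, 60_000, "-", "g", expression=1.0)],
                             )
        ap = tm.accessibility_field(plus)["chr1"]
        am = tm.accessibility_field(minus)["chr1"]
        # mirror around the shared genome midpoint maps one gene onto the other
        assert np.allclose(am, ap[::-1], atol=1e-12)


class TestTorsionField:
    def test_zero_expression_gives_zero_field(self):
        truth = manual_truth([tm.Gene("chr1", 40_000, 42_000, "+", "g",
                                      expression=0.0)])
        t = tm.torsion_field(truth)
        assert np.allclose(t.values(), 0.0)

    def test_upstream_tail_closed_form_at_one_decay_length(self):
        # TSS at 40005 puts TSS - lambda exactly on a bin center
        g = tm.Gene("chr1", 40_005, 42_005, "+", "g", expression=1.3)
        truth = manual_truth([g])
        p = truth.params
        t = tm.torsion_field(truth)
        k = int((g.tss - p.torsion_decay_bp) // 10)
        assert t["chr1"][k] == pytest.approx(
            p.tss_amplitude * 1.3 * np.exp(-1.0), rel=1e-12)

    def test_terminator_amplitude_scales_with_gene_length(self):
        short = manual_truth([tm.Gene("chr1", 30_000, 31_000, "+", "s",
                                      expression=1.0)])
        long = manual_truth([tm.Gene("chr1", 20_000, 31_000, "+", "l",
                                     expression=1.0)])
        p = short.params
        ts = tm.torsion_field(short)["chr1"]
        tl = tm.torsion_field(long)["chr1"]
        k = 31_000 // 10 + 5  # a bin shortly past the shared TES
        ratio = tl[k] / ts[k]
        expect = (p.tes_amplitude + p.tes_length_coeff * 11_000) / \
                 (p.tes_amplitude + p.tes_length_coeff * 1000)
        assert ratio == pytest.approx(expect, rel=1e-9)

    def test_insulation_truncates_midgap_torsion(self):
        # two identical divergent pairs; the second has an insulator at midgap
        def pair(offset, names):
            return [tm.Gene("chr1", offset, offset + 2000, "-", names[0],
                            expression=2.0),
                    tm.Gene("chr1", offset + 2600, offset + 4600, "+", names[1],
                            expression=2.0)]

        genes = pair(10_000, ("a1", "a2")) + pair(60_000, ("b1", "b2"))
        truth = manual_truth(genes)
        mid_free = 10_000 + 2000 + 300   # midgap of the free pair
        mid_ins = 60_000 + 2000 + 300
        truth.insulators = [("chr1", mid_ins)]
        truth.upstream_truncation = {"b1": 300, "b2": 300}
        t = tm.torsion_field(truth)["chr1"]
        amp = truth.params.tss_amplitude * 2.0
        lam = truth.params.torsion_decay_bp
        # free midgap bin center 12305: 305 bp from the left TSS (12000),
        # 295 bp from the right TSS (12600); both tails contribute
        assert t[mid_free // 10] == pytest.approx(
            amp * (np.exp(-305 / lam) + np.exp(-295 / lam)), rel=1e-12)
        # insulated midgap: the tail crossing the insulator is truncated
        assert t[mid_ins // 10] == pytest.approx(amp * np.exp(-295 / lam),
                                                 rel=1e-12)
        assert t[mid_ins // 10] < t[mid_free // 10]


class TestSampling:
    def test_kappa_zero_makes_conditions_identically_distributed(self):
        truth, _ = tm.simulate(small_params(kappa=0.0))
        rates = tm.expected_rates(truth)
        for c in truth.genome.names:
            assert np.allclose(rates["with"][c], rates["without"][c])

    def test_empirical_bin_means_match_rates(self):
        params = small_params(chromosome_length=20_000)
        truth = tm.make_genome_and_genes(params)
        tm.accessibility_field(truth)
        tm.torsion_field(truth)
        tm.sequence_field(truth)
        rates = tm.expected_rates(truth)["with"]["chr1"]
        rng = np.random.default_rng(33)
        draws = rng.poisson(np.tile(rates, (2000, 1)))
        se = np.sqrt(rates / 2000)
        ok = np.abs(draws.mean(axis=0) - rates) <= 3 * np.maximum(se, 1e-9)
        assert ok.mean() > 0.99  # ~3-sigma criterion per bin

    def test_total_count_matches_expected_within_3se(self):
        truth, tracks = tm.simulate(small_params())
        rates = tm.expected_rates(truth)
        for cond, reps in (("with", tracks["with"]), ("without", tracks["without"])):
            expect = sum(rates[cond][c].sum() for c in truth.genome.names)
            for rep in reps:
                total = rep.values().sum()
                assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_sampling_deterministic_given_seed(self):
        t1, k1 = tm.simulate(small_params())
        t2, k2 = tm.simulate(small_params())
        for c in t1.genome.names:
            assert np.array_equal(k1["with"][0][c], k2["with"][0][c])
            assert np.array_equal(k1["purified"][c], k2["purified"][c])


class TestCompanionFixtures:
    def test_noise_free_mrna_recovers_expression_exactly(self):
        truth, tracks = tm.simulate(small_params(mrna_noise_sd=0.0))
        genes = tm.expression_from_mrna(tracks["mrna_plus"], tracks["mrna_minus"],
                                        truth.genes)
        for got, g in zip(genes, truth.genes):
            assert got.expression == pytest.approx(g.expression, rel=1e-12)

    def test_loop_scores_track_boundary_positive_torsion(self, default_sim):
        truth, _ = default_sim
        w = truth.genome.bin_width
        recomputed = [np.mean([max(0.0, -truth.torsion[l.chrom][b // w])
                               for b in (l.left, l.right)])
                      for l in truth.loops]
        rho = spearmanr([l.score for l in truth.loops], recomputed).statistic
        assert rho == pytest.approx(1.0)

    def test_divergent_insulation_two_peaks_vs_unb_plateau(self, default_sim):
        from scipy.signal import find_peaks
        truth, _ = default_sim
        pairs = [p for p in truth.divergent_pairs if p.gap_end - p.gap_start >= 50]

        def n_body_peaks(subset):
            regions = [(p.chrom, p.gap_start, p.gap_end, "+") for p in subset]
            mat = tm.scaled_region_matrix(truth.torsion, regions,
                                          flank_bp=500, n_body_bins=50)
            mean, _, _ = tm.composite_profile(mat)
            body = mean[50:100]
            peaks, _ = find_peaks(body, prominence=0.05 * np.nanmax(body))
            return len(peaks)

        unb = [p for p in pairs if p.left.promoter_class == "UNB"
               and p.right.promoter_class == "UNB"]
        ins = [p for p in pairs if p.left.promoter_class in ("TFO", "STM")
               and p.right.promoter_class in ("TFO", "STM")]
        assert len(unb) >= 10 and len(ins) >= 10
        assert n_body_peaks(unb) == 1    # merged (-) torsion plateau
        assert n_body_peaks(ins) == 2    # decoupled promoter-proximal peaks

    def test_fixture_dir_round_trips_through_readers(self, tmp_path):
        truth, tracks = tm.simulate(small_params())
        manifest = tm.write_fixture_dir(truth, tracks, str(tmp_path))
        assert manifest["n_genes"] == len(truth.genes)
        genome = tm.GenomeIndex.from_chrom_sizes(
            str(tmp_path / "genome.chrom.sizes"))
        back = tm.read_bedgraph(str(tmp_path / "icl_with_torsion_rep1.bedgraph"),
                                genome)
        for c in genome.names:
            assert np.allclose(back[c], tracks["with"][0][c])
        genes = tm.read_genes(str(tmp_path / "genes.bed"))
        assert [g.name for g in genes] == [g.name for g in truth.genes]
        loops = tm.read_loops_tsv(str(tmp_path / "loops.tsv"))
        assert [(l.chrom, l.left, l.right) for l in loops] == \
            [(l.chrom, l.left, l.right) for l in truth.loops]


class TestEndToEndRecovery:
    def test_recovery_improves_with_depth(self):
        rs = []
        for scale in (3000.0, 10_000.0, 30_000.0):
            truth, tracks = tm.simulate(tm.SimulationParams(seed=1,
                                                            depth_scale=scale))
            tor = tm.compute_torsion(tracks["with"], tracks["without"])
            rs.append(tm.recovery_correlation(tor, truth))
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.8

    def test_zero_amplitude_null_consistent_with_noise(self):
        # no injected torsion: the composite peak-to-valley at real TSSs must
        # be typical of that at random anchor sets (permutation test)
        params = tm.SimulationParams(seed=5, tss_amplitude=0.0,
                                     tes_amplitude=0.0, tes_length_coeff=0.0)
        truth, tracks = tm.simulate(params)
        tor = tm.compute_torsion(tracks["with"], tracks["without"])
        anchors, _, _ = tm.anchors_from_genes(truth.genes, at="tss")

        def p2v(anchor_list):
            mat = tm.anchored_matrix(tor, anchor_list, flank_bp=1000)
            mean, _, _ = tm.composite_profile(mat)
            return np.nanmax(mean) - np.nanmin(mean)

        observed = p2v(anchors)
        rng = np.random.default_rng(99)
        null = []
        for _ in range(100):
            rand = [(truth.genome.names[rng.integers(len(truth.genome.names))],
                     int(rng.integers(2000, truth.params.chromosome_length - 2000)),
                     "+" if rng.random() < 0.5 else "-")
                    for _ in range(len(anchors))]
            null.append(p2v(rand))
        p_value = np.mean([n >= observed for n in null])
        assert p_value >= 0.05
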