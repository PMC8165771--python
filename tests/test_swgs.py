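"""GC correction and the genome-wide z-score against a healthy panel."""

import numpy as np
import pytest

from cftriage.errors import ComputationError, ConfigurationError, DegenerateInputError, DomainError
from cftriage.simulate import SimulationConfig, simulate_healthy_panel, simulate_patient
from cftriage.swgs import GenomeWideZScorer, classify_tf, gc_correct


class TestGcCorrect:
    def test_uniform_counts_uniform_gc_identity(self, small_genome):
        counts = np.full(small_genome.n_bins, 100)
        np.testing.assert_allclose(gc_correct(counts, small_genome), 1.0)

    def test_scale_invariance(self, toy_genome):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000, toy_genome.n_bins)
        np.testing.assert_allclose(
            gc_correct(counts, toy_genome), gc_correct(10 * counts, toy_genome), rtol=1e-12
        )

    def test_two_class_gc_bias_removed(self, small_genome):
        # hand-built bias: bins with gc >= median get 2x counts; after
        # decile-median correction both class medians return to 1.0
        genome = small_genome
        gc = np.where(np.arange(genome.n_bins) % 2 == 0, 0.3, 0.6)
        bins = genome.bins.copy()
        bins["gc"] = gc
        from cftriage.genome import GenomeDef

        g2 = GenomeDef(bins)
        counts = np.where(gc == 0.6, 2000, 1000)
        ratios = gc_correct(counts, g2)
        assert np.median(ratios[gc == 0.6]) == pytest.approx(1.0)
        assert np.median(ratios[gc == 0.3]) == pytest.approx(1.0)

    def test_all_zero_coverage_rejected(self, small_genome):
        with pytest.raises(DegenerateInputError):
            gc_correct(np.zeros(small_genome.n_bins), small_genome)

    def test_sparse_decile_falls_back_with_warning(self, small_genome):
        # 30 bins in 10 deciles -> 3 bins per decile, below the floor of 5
        counts = np.full(small_genome.n_bins, 50)
        bins = small_genome.bins.copy()
        bins["gc"] = np.linspace(0.2, 0.7, small_genome.n_bins)
        from cftriage.genome import GenomeDef

        with pytest.warns(UserWarning, match="global median"):
            gc_correct(counts, GenomeDef(bins))


def _hand_z(panel_segment_ratios, sample_ratios):
    """Independent arithmetic for the per-segment z vector."""
    mu = [sum(col) / len(col) for col in zip(*panel_segment_ratios)]
    sd = []
    for j, col in enumerate(zip(*panel_segment_ratios)):
        var = sum((x - mu[j]) ** 2 for x in col) / (len(col) - 1)
        sd.append(var**0.5)
    return [(sample_ratios[j] - mu[j]) / sd[j] for j in range(len(mu))]


class TestPerSegmentZ:
    def _counts_from_segment_levels(self, genome, levels):
        # constant counts within each segment; uniform GC makes correction a
        # plain median normalization
        idx = genome.segment_index()
        return np.array([levels[i] for i in idx], dtype=float) * 100

    def test_sample_at_panel_mean_scores_zero(self, small_genome):
        # exact at the definition level: segment ratios equal to the panel
        # means standardize to z = 0
        mu = np.array([1.0, 0.98, 1.02])
        sd = np.array([0.02, 0.03, 0.01])
        z = GenomeWideZScorer._zvec(mu.copy(), mu, sd, np.array(small_genome.segment_ids))
        np.testing.assert_allclose(z, 0.0)
        # end to end, the per-sample median renormalization shifts the mean
        # profile slightly, so the z vector is only near zero
        levels = [(0.98, 1.00, 1.02), (1.00, 1.04, 0.96), (1.03, 0.97, 1.00), (1.00, 1.06, 0.94)]
        panel = np.stack([self._counts_from_segment_levels(small_genome, lv) for lv in levels])
        scorer = GenomeWideZScorer(small_genome).fit(panel)
        z = scorer.score_sample(panel.mean(axis=0)).z_segments
        np.testing.assert_allclose(z, 0.0, atol=0.2)

    def test_hand_computed_fixture(self, small_genome):
        # 4 controls x 3 segments, ratios chosen so medians stay at segment 2
        levels = [(1.00, 1.02, 0.98), (1.04, 1.00, 0.96), (0.96, 0.98, 1.06), (1.02, 1.04, 0.94)]
        panel = np.stack([self._counts_from_segment_levels(small_genome, lv) for lv in levels])
        scorer = GenomeWideZScorer(small_genome).fit(panel)
        sample = self._counts_from_segment_levels(small_genome, (1.06, 0.96, 1.0))
        got = scorer.score_sample(sample).z_segments
        # oracle: recompute the normalized segment ratios and z by hand
        def seg_ratios(counts):
            rate = counts / counts.sum()
            ratios = rate / np.median(rate)
            return [float(np.mean(ratios[small_genome.segment_index() == j])) for j in range(3)]

        panel_ratios = [seg_ratios(p) for p in panel]
        expected = _hand_z(panel_ratios, seg_ratios(sample))
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_two_sigma_deviation_scores_two(self, small_genome):
        # definitional: a segment ratio at mu + 2*sigma standardizes to z = 2
        mu = np.array([1.0, 0.98, 1.02])
        sd = np.array([0.02, 0.03, 0.01])
        ids = np.array(small_genome.segment_ids)
        z = GenomeWideZScorer._zvec(mu + 2 * sd, mu, sd, ids)
        np.testing.assert_allclose(z, 2.0)

    def test_zero_panel_sd_names_segment(self, small_genome):
        levels = [(1.0, 1.0, 1.0)] * 4  # identical controls -> sd 0 everywhere
        panel = np.stack([self._counts_from_segment_levels(small_genome, lv) for lv in levels])
        with pytest.raises(ComputationError, match="segment"):
            GenomeWideZScorer(small_genome).fit(panel)


class TestGenomeWideZ:
    def _fit_scorer(self, genome, seed=11):
        cfg = SimulationConfig(seed=seed, n_healthy=8, n_reads_swgs=1_000_000, n_fragments=1000)
        panel = simulate_healthy_panel(cfg, genome)
        return GenomeWideZScorer(genome).fit(np.stack([h.bin_counts for h in panel]))

    def test_all_zero_zvec_gives_negative_z(self, small_genome):
        levels = [(1.00, 1.02, 0.98), (1.04, 1.00, 0.96), (0.96, 0.98, 1.06), (1.02, 1.04, 0.94)]
        panel = np.stack(
            [np.repeat([100 * x for x in lv], 10) for lv in levels]
        )
        scorer = GenomeWideZScorer(small_genome).fit(panel)
        # S = 0 corresponds to z-vector 0 -> Z = -mu_S / sd_S < 0
        z0 = (0.0 - scorer.s_mean_) / scorer.s_sd_
        assert z0 < 0
        assert z0 == pytest.approx(-scorer.s_mean_ / scorer.s_sd_)

    def test_leave_one_out_brute_force(self, small_genome):
        levels = [(1.00, 1.02, 0.98), (1.04, 1.00, 0.96), (0.96, 0.98, 1.06), (1.02, 1.04, 0.94)]
        panel = np.stack([np.repeat([100 * x for x in lv], 10) for lv in levels])
        scorer = GenomeWideZScorer(small_genome).fit(panel)

        def seg_ratios(counts):
            rate = counts / counts.sum()
            ratios = rate / np.median(rate)
            return np.array([np.mean(ratios[small_genome.segment_index() == j]) for j in range(3)])

        ratios = [seg_ratios(p) for p in panel]
        loo = []
        for j in range(4):
            rest = [ratios[i] for i in range(4) if i != j]
            mu = np.mean(rest, axis=0)
            sd = np.std(rest, axis=0, ddof=1)
            loo.append(float((((ratios[j] - mu) / sd) ** 2).sum()))
        np.testing.assert_allclose(sorted(scorer.loo_s_), sorted(loo), rtol=1e-10)
        assert scorer.s_mean_ == pytest.approx(np.mean(loo))
        assert scorer.s_sd_ == pytest.approx(np.std(loo, ddof=1))

    def test_held_out_healthy_in_normal_range(self, toy_genome):
        scorer = self._fit_scorer(toy_genome, seed=11)
        cfg = SimulationConfig(seed=99, n_healthy=6, n_reads_swgs=1_000_000, n_fragments=1000)
        zs = [scorer.score_sample(h.bin_counts).z for h in simulate_healthy_panel(cfg, toy_genome)]
        assert np.mean(np.abs(zs) < 3) >= 0.9

    def test_scale_invariance_of_z(self, toy_genome):
        scorer = self._fit_scorer(toy_genome)
        cfg = SimulationConfig(seed=21, n_reads_swgs=1_000_000, n_fragments=1000)
        s = simulate_patient(cfg, toy_genome, 0.1, "p")
        z1 = scorer.score_sample(s.bin_counts).z
        z2 = scorer.score_sample(s.bin_counts * 7).z
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_copy_number_neutral_blindness(self, toy_genome):
        # theta=0.3 with an all-diploid tumor: coverage carries no signal
        scorer = self._fit_scorer(toy_genome)
        flat = {f"seg{i:02d}": 2.0 for i in range(20)}
        zs = []
        for r in range(6):
            cfg = SimulationConfig(seed=40 + r, n_reads_swgs=1_000_000, n_fragments=1000)
            s = simulate_patient(cfg, toy_genome, 0.3, f"cn{r}", cna_profile=flat)
            zs.append(scorer.score_sample(s.bin_counts).z)
        assert np.mean(np.abs(zs)) < 3

    def test_unfitted_scorer_raises(self, small_genome):
        with pytest.raises(ComputationError):
            GenomeWideZScorer(small_genome).score_sample(np.ones(small_genome.n_bins))

    def test_small_panel_rejected(self, small_genome):
        with pytest.raises(ConfigurationError):
            GenomeWideZScorer(small_genome).fit(np.ones((3, small_genome.n_bins)))


class TestClassifyTf:
    @pytest.mark.parametrize(
        "z,expected_class", [(5.0, "high"), (4.99, "low"), (2.5, "low"), (-1.0, "low"), (30.0, "high")]
    )
    def test_threshold(self, z, expected_class):
        cls, _ = classify_tf(z)
        assert cls == expected_class

    def test_band_annotation(self):
        assert classify_tf(2.5)[1] == "~5-10% tumor fraction"
        assert classify_tf(5.0)[1] == "~>=10% tumor fraction"
        assert classify_tf(1.0)[1] == "~<5% tumor fraction"

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            classify_tf(float("nan"))
        with pytest.raises(DomainError):
            classify_tf(float("inf"))
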