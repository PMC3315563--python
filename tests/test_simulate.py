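"""Cohort simulator: truth structure, implants, fragments, expression."""

import numpy as np
import pytest
from scipy import stats

from medipseq.genome import generate_genome
from medipseq.simulate import (
    CohortDesign,
    ImplantedDmr,
    generate_truth,
    promoter_methylation,
    simulate_expression,
    simulate_fragments,
)


def _group_rows(truth, group):
    return [i for i, s in enumerate(truth.samples) if truth.group_labels[s] == group]


class TestGenerateTruth:
    def test_scores_in_unit_interval(self, truth):
        assert truth.scores.min() >= 0 and truth.scores.max() <= 1

    def test_implanted_deltas_at_least_quarter(self, truth):
        assert (truth.implanted.delta.abs() >= 0.25).all()

    def test_implant_shifts_group_mean_by_planned_delta(self, genome):
        cgi = genome.features("cgi").iloc[7]
        plan = [ImplantedDmr(cgi.feature_id, ("t(8;21)",), 0.4)]
        t = generate_truth(genome, CohortDesign(dmr_plan=plan), seed=11)
        lo, hi = genome.grid.overlapping_windows(cgi.chrom, cgi.start, cgi.end)
        win = genome.grid.flat_index(cgi.chrom, np.arange(lo, hi))
        fg = t.scores[np.ix_(_group_rows(t, "t(8;21)"), win)].mean()
        others = [i for i in range(len(t.samples)) if i not in _group_rows(t, "t(8;21)")]
        bg = t.scores[np.ix_(others, win)].mean()
        se = t.noise_sd / np.sqrt(len(win) * 3)
        assert abs((fg - bg) - 0.4) < 2 * se + 0.01

    def test_empty_plan_no_group_differences(self, genome):
        t = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=12)
        # group means are identical by construction; sample means differ only by noise
        assert np.allclose(t.group_means, t.group_means[0])
        for g in t.group_names:
            rows = _group_rows(t, g)
            diff = t.scores[rows].mean(axis=0) - t.group_means[0]
            sd = t.noise_sd / np.sqrt(len(rows))
            assert np.abs(diff).max() < 5 * sd  # ~3 sigma with clipping slack

    def test_gene_body_high_fraction_in_band(self, truth):
        gb = truth.class_windows("gene_body")
        frac = (truth.scores[:, gb] > 0.6).mean()
        assert 0.75 <= frac <= 0.9

    def test_sine_top_band_highest_in_nbm_depleted_in_aml(self, truth):
        sine = truth.class_windows("SINE")
        edges = [0, 0.2, 0.4, 0.6, 0.8, 1.0 + 1e-9]
        nbm = truth.scores[np.ix_(_group_rows(truth, "NBM"), sine)].ravel()
        aml_rows = [i for i in range(len(truth.samples)) if i not in _group_rows(truth, "NBM")]
        aml = truth.scores[np.ix_(aml_rows, sine)].ravel()
        h_nbm = np.histogram(nbm, bins=edges)[0] / len(nbm) * 100
        h_aml = np.histogram(aml, bins=edges)[0] / len(aml) * 100
        assert h_nbm.argmax() == 4  # >0.8 band highest in NBM-like samples
        assert h_nbm[4] - h_aml[4] >= 15  # visibly depleted in AML-like samples

    def test_unknown_feature_in_plan_raises(self, genome):
        with pytest.raises(ValueError, match="unknown feature"):
            generate_truth(genome, CohortDesign(dmr_plan=[ImplantedDmr("nope", ("NK",), 0.4)]), seed=1)

    def test_determinism(self, genome):
        a = generate_truth(genome, CohortDesign(), seed=5)
        b = generate_truth(genome, CohortDesign(), seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestSimulateFragments:
    def test_exact_count_and_bounds(self, genome, truth):
        fs = simulate_fragments(genome, truth, "nbm_1", 10, seed=3)
        assert len(fs) == 10
        for _, row in fs.records.iterrows():
            assert 0 <= row.start < row.end <= genome.chrom_lengths[row.chrom]

    def test_fully_methylated_counts_track_cpg_density(self, genome):
        # truth == 1 everywhere, no background: per-window coverage must
        # correlate strongly with local CpG content at ~30x depth
        t = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=1)
        t.scores[:] = 1.0
        fs = simulate_fragments(genome, t, t.samples[0], 67_000, background_rate=0.0,
                                seed=1, duplicate_frac=0.0, lowq_frac=0.0)
        cov = fs.center_coverage(genome.grid)
        from medipseq.coupling import compute_coupling

        ct = compute_coupling(genome, 450.0).ctot_flat()
        r = stats.pearsonr(cov, ct).statistic
        assert r > 0.9

    def test_unmethylated_background_is_uniform(self, genome):
        t = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=1)
        t.scores[:] = 0.0
        n = 60_000  # >= 50 fragments per 10-kb bin
        fs = simulate_fragments(genome, t, t.samples[0], n, background_rate=0.02,
                                seed=1, duplicate_frac=0.0, lowq_frac=0.0)
        counts = []
        for chrom, sub in fs.records.groupby("chrom"):
            binned = np.bincount(sub.start // 10_000,
                                 minlength=genome.chrom_lengths[chrom] // 10_000)
            counts.extend(binned[: genome.chrom_lengths[chrom] // 10_000])
        counts = np.asarray(counts)
        assert counts.min() >= 50
        assert counts.max() / counts.min() < 2

    def test_zero_measure_raises(self, genome):
        t = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=1)
        t.scores[:] = 0.0
        with pytest.raises(ValueError, match="sampling measure"):
            simulate_fragments(genome, t, t.samples[0], 100, background_rate=0.0, seed=1)

    def test_contamination_fractions(self, genome, truth):
        fs = simulate_fragments(genome, truth, "nk_1", 10_000, seed=9)
        assert fs.records.is_duplicate.sum() == 500
        assert (fs.records.mapq < 10).sum() == 500


class TestSimulateExpression:
    def test_noise_free_coupling_gives_perfect_inverse(self, genome, truth):
        expr = simulate_expression(truth, genome, coupling_strength=-4.0, noise_sd=0.0, seed=1)
        meth = promoter_methylation(truth, genome)
        for gene in expr.index[:10]:
            r = stats.pearsonr(meth.loc[gene], expr.loc[gene]).statistic
            assert r == pytest.approx(-1.0, abs=1e-9)

    def test_null_coupling_correlations_small(self):
        g = generate_genome(seed=21, n_chroms=2, chrom_length=1_200_000, n_genes=120,
                            n_repeats_per_class=20)
        t = generate_truth(g, CohortDesign(dmr_plan=[]), seed=21)
        expr = simulate_expression(t, g, coupling_strength=0.0, noise_sd=0.5, seed=21)
        meth = promoter_methylation(t, g)
        rs = np.array([
            stats.pearsonr(meth.loc[gene], expr.loc[gene]).statistic for gene in expr.index
        ])
        # exact null: P(|r| < 0.3) at n=16 from the t transform of r
        tcrit = 0.3 * np.sqrt(14) / np.sqrt(1 - 0.09)
        p0 = 1 - 2 * stats.t.sf(tcrit, 14)
        frac = (np.abs(rs) < 0.3).mean()
        assert abs(frac - p0) < 3 * np.sqrt(p0 * (1 - p0) / len(rs))

    def test_determinism_and_seed_sensitivity(self, genome, truth):
        a = simulate_expression(truth, genome, seed=4)
        b = simulate_expression(truth, genome, seed=4)
        c = simulate_expression(truth, genome, seed=5)
        assert a.equals(b)
        assert not a.equals(c)
        assert a.notna().all().all()
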