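"""Quantifier: calibration recovery, posterior oracle, saturation, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipseq.batman import (
    BatmanModel,
    CalibrationError,
    InferenceConfig,
    calibrate_scale,
    correlate_with_reference,
    quantify_methylome,
    saturation_analysis,
)
from medipseq.coupling import compute_coupling
from medipseq.fragments import FRAGMENT_COLUMNS, FragmentSet
from medipseq.genome import ANNOTATION_COLUMNS, GenomeSpec
from medipseq.simulate import CohortDesign, generate_truth, simulate_fragments
from medipseq.track import MethylomeTrack


def _constant_truth(genome, value, seed=1):
    t = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=seed)
    t.scores[:] = value
    return t


@pytest.fixture(scope="module")
def small_coupling(small_genome):
    return compute_coupling(small_genome, 450.0)


class TestCalibration:
    def test_fully_methylated_rate_recovery(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 1.0)
        n = 20_000
        fs = simulate_fragments(small_genome, truth, truth.samples[0], n,
                                background_rate=0.0, seed=1,
                                duplicate_frac=0.0, lowq_frac=0.0)
        cal = calibrate_scale(fs, small_coupling)
        # with m == 1 the generator's fragments-per-coupling rate is
        # n_fragments / n_anchorable_cpgs
        n_cpg = sum(
            (small_genome.cpg_positions[c] < small_genome.grid.n_windows(c) * 100).sum()
            for c in small_genome.grid.chroms
        )
        r_true = n / n_cpg
        assert abs(cal.r - r_true) / r_true < 0.15

    def test_doubling_fragments_doubles_rate(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 1.0)
        cals = []
        for n in (15_000, 30_000):
            fs = simulate_fragments(small_genome, truth, truth.samples[0], n,
                                    background_rate=0.0, seed=2,
                                    duplicate_frac=0.0, lowq_frac=0.0)
            cals.append(calibrate_scale(fs, small_coupling))
        ratio = cals[1].r / cals[0].r
        assert abs(ratio - 2.0) < 0.2

    def test_all_zero_coverage_is_calibration_error(self, small_genome, small_coupling):
        fs = FragmentSet("s", pd.DataFrame([], columns=FRAGMENT_COLUMNS))
        with pytest.raises(CalibrationError):
            calibrate_scale(fs, small_coupling)


def _sparse_cluster_genome(n_clusters=60, spacing=1500, cpgs_per_cluster=6):
    """Isolated CpG clusters, each inside a single window, spaced beyond the
    fragment length so no two clusters share any coupling."""
    length = (n_clusters + 2) * spacing
    pos = []
    for i in range(n_clusters):
        base = (i + 1) * spacing + 40
        pos.extend(base + 2 * np.arange(cpgs_per_cluster))
    ann = pd.DataFrame([], columns=ANNOTATION_COLUMNS)
    tss = pd.DataFrame([], columns=["gene_id", "chrom", "pos", "strand"])
    return GenomeSpec({"chr1": length}, {"chr1": np.asarray(pos, dtype=np.int64)}, ann, tss)


class TestUncoupledOracle:
    def test_posterior_median_matches_truncated_normal(self):
        """On a CpG-sparse genome each cluster window's posterior is the
        closed-form truncated Normal; the sampler must agree within 0.02."""
        genome = _sparse_cluster_genome()
        coupling = compute_coupling(genome, 450.0)
        truth = generate_truth(genome, CohortDesign(dmr_plan=[]), seed=3)
        levels = np.array([0.15, 0.3, 0.5, 0.7, 0.85])
        cluster_windows = np.flatnonzero(coupling.cpg_count_flat() > 0)
        values = np.empty(genome.grid.total_windows)
        values[:] = 0.5
        for k, w in enumerate(cluster_windows):
            values[w] = levels[k % len(levels)]
        truth.scores[:] = values
        fs = simulate_fragments(genome, truth, truth.samples[0], 12_000,
                                background_rate=0.02, seed=4,
                                duplicate_frac=0.0, lowq_frac=0.0)
        cfg = InferenceConfig(burn_in=400, draws=3000)
        model = BatmanModel(fs, coupling, cfg)
        res = model.fit(seed=5)
        cal = res.calibration
        # reproduce the model's own heteroscedastic weights
        y = fs.center_coverage(genome.grid).astype(float)
        y_smooth = np.convolve(y, np.ones(5) / 5.0, mode="same")
        sigw = np.sqrt(np.maximum(y_smooth, 2.0))
        grid_m = np.linspace(0.0, 1.0, 2001)
        K = coupling.halfwidth
        band = coupling.band["chr1"]
        n = genome.grid.n_windows("chr1")
        checked = 0
        for w in cluster_windows:
            if not np.isfinite(res.track.score[w]):
                continue
            logp = np.zeros_like(grid_m)
            for p in range(max(0, w - K), min(n, w + K + 1)):
                c = band[p, K + w - p]
                if c > 0:
                    mu = cal.r * c * grid_m + cal.b
                    logp += -0.5 * ((y[p] - mu) / sigw[p]) ** 2
            dens = np.exp(logp - logp.max())
            cdf = np.cumsum(dens)
            cdf /= cdf[-1]
            oracle_median = grid_m[np.searchsorted(cdf, 0.5)]
            assert abs(res.track.score[w] - oracle_median) <= 0.02
            checked += 1
        assert checked >= 40


class TestQuantifyRecovery:
    def test_fully_methylated_scores_high(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 1.0)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 15_000,
                                background_rate=0.02, seed=6,
                                duplicate_frac=0.0, lowq_frac=0.0)
        track = quantify_methylome(fs, small_coupling, seed=7)
        assert np.nanmean(track.score) >= 0.85

    def test_unmethylated_scores_low(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.0)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 15_000,
                                background_rate=0.02, seed=8,
                                duplicate_frac=0.0, lowq_frac=0.0)
        track = quantify_methylome(fs, small_coupling, seed=9)
        assert np.nanmean(track.score) <= 0.15

    def test_low_coupling_windows_missing_regardless_of_coverage(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.8)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 15_000,
                                background_rate=0.10, seed=10,
                                duplicate_frac=0.0, lowq_frac=0.0)
        track = quantify_methylome(fs, small_coupling, seed=11)
        ct = small_coupling.ctot_flat()
        low = ct < 0.5
        assert np.isnan(track.score[low]).all()
        assert (track.coverage[low] > 0).any()  # missing despite coverage

    def test_missingness_monotone_in_cmin(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.9)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 10_000, seed=12)
        strict = quantify_methylome(fs, small_coupling, InferenceConfig(c_min=2.0, draws=100, burn_in=50), seed=13)
        loose = quantify_methylome(fs, small_coupling, InferenceConfig(c_min=0.5, draws=100, burn_in=50), seed=13)
        assert (loose.callable_mask | ~strict.callable_mask).all()


class TestSaturation:
    def test_forced_identical_subsets_give_r_one(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.9)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 10_000, seed=14)
        idx = np.arange(len(fs))
        out = saturation_analysis(fs, small_coupling, [0.25, 0.5], seed=0,
                                  config=InferenceConfig(draws=200, burn_in=100),
                                  halves=(idx, idx))
        assert (out.pearson_r > 0.999).all()

    def test_reproducibility_nondecreasing_with_depth(self, small_genome, small_coupling, truth, genome):
        t = generate_truth(small_genome, CohortDesign(dmr_plan=[]), seed=15)
        fs = simulate_fragments(small_genome, t, t.samples[0], 24_000, seed=16)
        cfg = InferenceConfig(draws=300, burn_in=100)
        lows, highs = [], []
        for s in range(3):
            out = saturation_analysis(fs, small_coupling, [0.1, 0.5], seed=s, config=cfg)
            lows.append(out.pearson_r.iloc[0])
            highs.append(out.pearson_r.iloc[1])
        assert np.median(highs) >= np.median(lows)

    def test_fraction_above_half_rejected(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.9)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 1_000, seed=17)
        with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
            saturation_analysis(fs, small_coupling, [0.25, 0.6])

    def test_unstable_grid_point_flagged(self, small_genome, small_coupling):
        truth = _constant_truth(small_genome, 0.9)
        fs = simulate_fragments(small_genome, truth, truth.samples[0], 5_000, seed=18)
        out = saturation_analysis(
            fs, small_coupling, [0.25, 0.5], seed=0,
            config=InferenceConfig(draws=100, burn_in=50),
            min_callable=10**6,
        )
        assert (~out.stable).all()
        assert out.pearson_r.isna().all()


class TestReferenceCorrelation:
    def _truth_track(self, genome, truth, sample):
        scores = truth.sample_scores(sample).astype(float)
        return MethylomeTrack(sample, genome.grid, scores, np.zeros_like(scores),
                              np.zeros(genome.grid.total_windows, dtype=np.int64))

    def _cpg_reference(self, genome, values):
        rows = []
        for chrom in genome.grid.chroms:
            pos = genome.cpg_positions[chrom]
            widx = genome.grid.window_of(chrom, pos)
            keep = widx >= 0
            flat = genome.grid.flat_index(chrom, widx[keep])
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos[keep], "fraction": values[flat]}))
        return pd.concat(rows, ignore_index=True)

    def test_noise_free_track_gives_perfect_correlation(self, genome, truth):
        track = self._truth_track(genome, truth, truth.samples[0])
        ref = self._cpg_reference(genome, truth.sample_scores(truth.samples[0]))
        out = correlate_with_reference(track, ref)
        assert out.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_reference_errors(self, genome, truth):
        track = self._truth_track(genome, truth, truth.samples[0])
        ref = self._cpg_reference(genome, truth.sample_scores(truth.samples[0]))
        ref["fraction"] = 0.5
        with pytest.raises(ValueError):
            correlate_with_reference(track, ref)

    def test_all_sites_missing_errors(self, genome, truth):
        scores = np.full(genome.grid.total_windows, np.nan)
        track = MethylomeTrack("s", genome.grid, scores, scores.copy(),
                               np.zeros(genome.grid.total_windows, dtype=np.int64))
        ref = self._cpg_reference(genome, truth.sample_scores(truth.samples[0]))
        with pytest.raises(ValueError, match="missing windows"):
            correlate_with_reference(track, ref)
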