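"""Copy-number module: normalization, segmentation, tumor-fraction fit,
state classification, and cross-depth concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats

from cfpipe import cnv
from cfpipe import simulate as sim


def profile_from_log2r(values, chrom="chr1", bin_size=10**6):
    rows = [
        {"chrom": chrom, "start": i * bin_size, "end": (i + 1) * bin_size,
         "log2r": v}
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


def analyze(spec, seed, sample_noise=True, penalty=12.0):
    tumor, normal = sim.gen_bin_profile(spec, seed, sample_noise=sample_noise)
    lr = cnv.normalize_bins(tumor, normal)
    segments = cnv.segment_profile(lr, penalty=penalty)
    sd = cnv.estimate_noise_sd(lr) if sample_noise else None
    return cnv.estimate_tf(segments, bin_noise_sd=sd)


class TestNormalizeBins:
    def test_identical_profiles_give_zero(self):
        spec = sim.ProfileSpec(tumor_fraction=0.0)
        tumor, _ = sim.gen_bin_profile(spec, seed=0)
        lr = cnv.normalize_bins(tumor, tumor)
        np.testing.assert_allclose(lr["log2r"], 0.0)

    def test_scale_invariance(self):
        spec = sim.ProfileSpec()
        tumor, normal = sim.gen_bin_profile(spec, seed=1)
        doubled = cnv.BinProfile(tumor.bins.assign(count=tumor.bins["count"] * 2))
        lr1 = cnv.normalize_bins(tumor, normal)
        lr2 = cnv.normalize_bins(doubled, normal)
        np.testing.assert_allclose(lr1["log2r"], lr2["log2r"])

    def test_noise_free_segment_mean_matches_closed_form(self):
        spec = sim.ProfileSpec(
            tumor_fraction=0.25,
            segments=[sim.CNSegment("chr3", 30_000_000, 90_000_000, c=4, phi=1.0)],
        )
        tumor, normal = sim.gen_bin_profile(spec, seed=0, sample_noise=False)
        lr = cnv.normalize_bins(tumor, normal)
        inside = (
            (lr["chrom"] == "chr3")
            & (lr["start"] >= 30_000_000)
            & (lr["end"] <= 90_000_000)
        )
        assert lr.loc[inside, "log2r"].mean() == pytest.approx(np.log2(1.25), abs=1e-9)

    def test_grid_mismatch_rejected(self):
        spec = sim.ProfileSpec()
        tumor, normal = sim.gen_bin_profile(spec, seed=0)
        with pytest.raises(ValueError, match="grids differ"):
            cnv.normalize_bins(tumor, cnv.BinProfile(normal.bins.iloc[:-1]))


class TestMixtureModel:
    def test_pure_tumor_limit(self):
        for c in range(1, 9):
            assert cnv.model_log2r(c, 1.0, 1.0 - 1e-12) == pytest.approx(
                np.log2(c / 2), abs=1e-9
            )

    def test_zero_tumor_fraction_limit(self):
        for c in range(9):
            for phi in (0.25, 0.5, 1.0):
                assert cnv.model_log2r(c, phi, 0.0) == 0.0


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        rng = np.random.default_rng(0)
        lr = profile_from_log2r(rng.normal(0, 0.05, 120))
        segments = cnv.segment_profile(lr)
        assert len(segments) == 1
        assert segments[0].n_bins == 120

    @pytest.mark.parametrize("seed", range(5))
    def test_single_step_breakpoint_located(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 0.05, 60), rng.normal(1.0, 0.05, 60)])
        segments = cnv.segment_profile(profile_from_log2r(x))
        assert len(segments) == 2
        boundary_bin = segments[0].n_bins
        assert abs(boundary_bin - 60) <= 2

    def test_two_step_staircase_three_segments(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(0, 0.05, 50), rng.normal(0.8, 0.05, 40), rng.normal(-0.5, 0.05, 50)]
        )
        segments = cnv.segment_profile(profile_from_log2r(x))
        assert len(segments) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_near_optimal_vs_exhaustive_two_changepoints(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, min_bins = 150, 10
        x = np.concatenate(
            [rng.normal(0, 0.1, 50), rng.normal(0.7, 0.1, 50), rng.normal(0.1, 0.1, 50)]
        )

        def sse_for(breaks):
            pieces = np.split(x, breaks)
            return sum(((p - p.mean()) ** 2).sum() for p in pieces)

        best = min(
            sse_for([i, j])
            for i in range(min_bins, n - 2 * min_bins + 1)
            for j in range(i + min_bins, n - min_bins + 1)
        )
        segments = cnv.segment_profile(profile_from_log2r(x), min_bins=min_bins)
        breaks = np.cumsum([s.n_bins for s in segments])[:-1]
        assert sse_for(list(breaks)) <= 1.05 * best

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            cnv.segment_profile(profile_from_log2r([]))


class TestEstimateTF:
    @pytest.mark.parametrize("tf", [0.1, 0.2, 0.25, 0.3, 0.4, 0.5])
    def test_noise_free_recovery(self, tf):
        spec = sim.ProfileSpec(
            tumor_fraction=tf,
            segments=[
                sim.CNSegment("chr8", 30_000_000, 110_000_000, c=1),
                sim.CNSegment("chr10", 40_000_000, 100_000_000, c=3),
                sim.CNSegment("chr12", 20_000_000, 70_000_000, c=4),
            ],
        )
        est, _ = analyze(spec, seed=0, sample_noise=False)
        assert abs(est.tumor_fraction - tf) <= 0.03

    def test_all_neutral_profile_gives_zero(self):
        spec = sim.ProfileSpec(tumor_fraction=0.0, segments=[])
        est, fitted = analyze(spec, seed=0, sample_noise=False)
        assert est.tumor_fraction == 0.0
        assert all(s.state == "neutral" for s in fitted)

    def test_pre_surgery_scenario_no_tumor_fraction(self):
        # noisy deep profile with no copy-number events
        spec = sim.ProfileSpec(tumor_fraction=0.0, segments=[])
        est, _ = analyze(spec, seed=3)
        assert est.tumor_fraction == 0.0

    def test_noise_free_default_truth_recovered(self):
        spec = sim.ProfileSpec()
        est, fitted = analyze(spec, seed=0, sample_noise=False)
        assert est.tumor_fraction == pytest.approx(0.25, abs=0.01)
        by_chrom = {
            s.chrom: s for s in fitted if s.state and s.state != "neutral"
        }
        assert by_chrom["chr8"].state == "clonal loss"
        assert by_chrom["chr10"].state == "clonal gain"
        assert by_chrom["chr16"].state == "subclonal gain"
        assert by_chrom["chr4"].state == "subclonal loss"
        assert est.frac_genome_subclonal == pytest.approx(140 / 3000, rel=0.05)

    def test_no_segments_rejected(self):
        with pytest.raises(ValueError):
            cnv.estimate_tf([])


class TestClassifySegments:
    def seg(self, mean, n_bins=50):
        return cnv.Segment("chr1", 0, n_bins * 10**6, n_bins, mean)

    def test_clonal_gain(self):
        (out,) = cnv.classify_segments([self.seg(cnv.model_log2r(4, 1.0, 0.25))], 0.25)
        assert (out.state, out.c, out.phi) == ("clonal gain", 4, 1.0)

    def test_subclonal_loss(self):
        (out,) = cnv.classify_segments([self.seg(cnv.model_log2r(1, 0.5, 0.25))], 0.25)
        assert (out.state, out.c, out.phi) == ("subclonal loss", 1, 0.5)

    def test_neutral(self):
        (out,) = cnv.classify_segments([self.seg(0.0)], 0.25)
        assert out.state == "neutral"

    def test_degenerate_fit_prefers_clonal(self):
        # c=3 clonal and c=4, phi=0.5 predict the same log2R at any TF
        mean = cnv.model_log2r(4, 0.5, 0.25)
        assert mean == pytest.approx(cnv.model_log2r(3, 1.0, 0.25))
        (out,) = cnv.classify_segments([self.seg(mean)], 0.25)
        assert (out.state, out.c, out.phi) == ("clonal gain", 3, 1.0)


class TestConcordance:
    def truth(self):
        return sim.truth_segments(sim.ProfileSpec())

    def test_identical_call_sets(self):
        report = cnv.concordance(self.truth(), self.truth())
        assert report["clonal_concordance"] == 1.0
        assert report["false_subclonal"] == 0
        assert report["missed_subclonal"] == 0
        assert report["clonality_swaps"] == 0

    def test_extra_subclonal_event_counted_false(self):
        extra = self.truth() + [
            cnv.Segment("chr2", 10_000_000, 40_000_000, 30, 0.05,
                        state="subclonal gain", c=3, phi=0.25)
        ]
        report = cnv.concordance(self.truth(), extra)
        assert report["false_subclonal"] == 1

    def test_missing_subclonal_event_counted_missed(self):
        without = [s for s in self.truth() if s.chrom != "chr16"]
        report = cnv.concordance(self.truth(), without)
        assert report["missed_subclonal"] == 1

    def test_clonality_swap_detected(self):
        swapped = []
        for s in self.truth():
            if s.chrom == "chr8":
                s = cnv.Segment(s.chrom, s.start, s.end, s.n_bins, s.mean_log2r,
                                state="subclonal loss", c=s.c, phi=0.5)
            swapped.append(s)
        report = cnv.concordance(self.truth(), swapped)
        assert report["clonality_swaps"] == 1


@pytest.fixture(scope="module")
def false_subclonal_by_depth():
    truth = sim.truth_segments(sim.ProfileSpec())
    counts = {}
    for depth in (147, 117, 94, 75, 60, 10):
        per_seed = []
        for seed in range(20):
            spec = sim.ProfileSpec(mean_reads_per_bin=10.0 * depth)
            est, fitted = analyze(spec, seed=seed)
            per_seed.append(cnv.concordance(truth, fitted)["false_subclonal"])
        counts[depth] = np.array(per_seed)
    return counts


class TestDepthDegradation:

    def test_low_pass_worse_than_deep(self, false_subclonal_by_depth):
        assert (
            false_subclonal_by_depth[10].mean()
            > false_subclonal_by_depth[147].mean()
        )

    def test_nonincreasing_trend_in_depth(self, false_subclonal_by_depth):
        depths = sorted(false_subclonal_by_depth)
        means = [false_subclonal_by_depth[d].mean() for d in depths]
        tau, _ = scistats.kendalltau(depths, means)
        assert tau < 0


class TestSegmentIO:
    def test_round_trip_files(self, tmp_path):
        spec = sim.ProfileSpec()
        tumor, normal = sim.gen_bin_profile(spec, seed=0)
        cnv.write_bins_tsv(tumor, tmp_path / "t.tsv")
        back = cnv.read_bins_tsv(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(
            back.bins, tumor.bins, check_dtype=False
        )
        est, fitted = analyze(spec, seed=0)
        cnv.write_segments_tsv(fitted, tmp_path / "segs.tsv")
        segs = pd.read_csv(tmp_path / "segs.tsv", sep="\t")
        assert len(segs) == len(fitted)
        assert {"chrom", "start", "end", "state", "c", "phi"} <= set(segs.columns)
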