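"""Coverage uniformity metrics against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from l1audit import coverage as cov
from l1audit import synthetic
from l1audit.records import CoverageTrack, Log2RatioTrack, ValidationError


def _track(depths, bin_bp=1000, contig="chr1", scheme="fixed_width"):
    n = len(depths)
    starts = np.arange(n) * bin_bp
    return CoverageTrack(
        bins=pd.DataFrame(
            {"contig": contig, "start": starts, "end": starts + bin_bp,
             "depth": np.asarray(depths, dtype=float)}
        ),
        bin_scheme=scheme,
    )


def _log2(values, contig="chr1"):
    n = len(values)
    starts = np.arange(n) * 1000
    return Log2RatioTrack(
        bins=pd.DataFrame(
            {"contig": contig, "start": starts, "end": starts + 1000,
             "log2_ratio": np.asarray(values, dtype=float)}
        )
    )


class TestEqualReadBins:
    def test_uniform_reference_equal_widths(self):
        ref = _track([10.0] * 100, bin_bp=10_000)
        bins = cov.equal_read_bins(ref, target_bin_bp=100_000)
        widths = (bins["end"] - bins["start"]).unique()
        assert list(widths) == [100_000]

    def test_double_depth_region_halves_width(self):
        depths = [10.0] * 50 + [20.0] * 50
        ref = _track(depths, bin_bp=10_000)
        bins = cov.equal_read_bins(ref, target_bin_bp=250_000)
        widths = (bins["end"] - bins["start"]).to_numpy()
        # deep half gets proportionally narrower bins
        assert widths[-1] < widths[0]

    def test_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            depths = rng.integers(1, 50, size=200).astype(float)
            ref = _track(depths, bin_bp=1000)
            target = 20_000
            bins = cov.equal_read_bins(ref, target_bin_bp=target)
            # oracle: walk cumulative sums by hand
            n_bins = max(1, round(200 * 1000 / target))
            cum = np.cumsum(depths)
            targets = cum[-1] * np.arange(1, n_bins) / n_bins
            edges = [0]
            for t in targets:
                i = int(np.searchsorted(cum, t, side="left"))
                e = (i + 1) * 1000
                if e > edges[-1]:
                    edges.append(e)
            if edges[-1] < 200 * 1000:
                edges.append(200 * 1000)
            expected = list(zip(edges[:-1], edges[1:]))
            got = list(zip(bins["start"], bins["end"]))
            assert got == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            cov.equal_read_bins(_track([0.0] * 10))


class TestNormalizedLog2:
    def _bins(self, n=20, contig="chr1", bin_bp=1000):
        starts = np.arange(n) * bin_bp
        return pd.DataFrame(
            {"contig": contig, "start": starts, "end": starts + bin_bp}
        )

    def test_identity_gives_zero(self):
        t = _track([40.0] * 20)
        out = cov.normalized_log2(t, t, self._bins())
        assert np.allclose(out.values, 0.0)

    def test_doubled_sample_centered_back_to_zero(self):
        ref = _track([40.0] * 20)
        smp = _track([80.0] * 20)
        out = cov.normalized_log2(smp, ref, self._bins())
        assert np.allclose(out.values, 0.0)
        assert out.metadata["autosomal_median_centered"]

    def test_chrx_recentered_to_own_median(self):
        depths_ref = pd.concat([
            _track([40.0] * 20, contig="chr1").bins,
            _track([40.0] * 10, contig="chrX").bins,
        ]).reset_index(drop=True)
        depths_smp = pd.concat([
            _track([40.0] * 20, contig="chr1").bins,
            _track([20.0] * 10, contig="chrX").bins,  # female vs male ref
        ]).reset_index(drop=True)
        ref = CoverageTrack(bins=depths_ref)
        smp = CoverageTrack(bins=depths_smp)
        bins = pd.concat(
            [self._bins(20, "chr1"), self._bins(10, "chrX")]
        ).reset_index(drop=True)
        out = cov.normalized_log2(smp, ref, bins, chrx_to_own_median=True)
        chrx = out.bins["contig"] == "chrX"
        assert np.median(out.values[chrx]) == pytest.approx(0.0, abs=1e-12)

    def test_chry_zeroed(self):
        ref = CoverageTrack(bins=pd.concat([
            _track([40.0] * 20, contig="chr1").bins,
            _track([40.0] * 5, contig="chrY").bins,
        ]).reset_index(drop=True))
        smp = CoverageTrack(bins=pd.concat([
            _track([40.0] * 20, contig="chr1").bins,
            _track([1.0] * 5, contig="chrY").bins,
        ]).reset_index(drop=True))
        bins = pd.concat(
            [self._bins(20, "chr1"), self._bins(5, "chrY")]
        ).reset_index(drop=True)
        out = cov.normalized_log2(smp, ref, bins, chry_zero=True)
        assert (out.values[out.bins["contig"] == "chrY"] == 0.0).all()


class TestMapdMdad:
    def test_constant_track_zero(self):
        assert cov.mapd(_log2([0.3] * 10)) == 0.0
        assert cov.mdad(_log2([0.3] * 10)) == 0.0

    def test_alternating_closed_form(self):
        a = 0.4
        values = [a if i % 2 == 0 else -a for i in range(20)]
        assert cov.mapd(_log2(values)) == pytest.approx(2 * a)

    def test_mdad_small_example(self):
        assert cov.mdad(_log2([0.0, 0.0, 0.0, 1.0])) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            v = rng.normal(0, 0.5, 1000)
            track = _log2(v)
            mapd_oracle = float(np.median(
                [abs(v[i + 1] - v[i]) for i in range(len(v) - 1)]
            ))
            med = float(np.median(v))
            mdad_oracle = float(np.median([abs(x - med) for x in v]))
            assert abs(cov.mapd(track) - mapd_oracle) < 1e-12
            assert abs(cov.mdad(track) - mdad_oracle) < 1e-12

    def test_adjacent_pairs_never_cross_contigs(self):
        bins = pd.concat([
            _log2([0.0, 0.0], contig="chr1").bins,
            _log2([5.0, 5.0], contig="chr2").bins,
        ]).reset_index(drop=True)
        track = Log2RatioTrack(bins=bins)
        assert cov.mapd(track) == 0.0  # the 0->5 jump spans a contig boundary

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 0.3, 500)
        assert cov.mapd(_log2(v)) == pytest.approx(cov.mapd(_log2(v + 2.5)))
        assert cov.mdad(_log2(v)) == pytest.approx(cov.mdad(_log2(v + 2.5)))


class TestLorenzGini:
    def test_even_coverage_on_diagonal(self):
        curve, gini = cov.lorenz_gini(_track([25.0] * 40))
        assert gini == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(curve[:, 0], curve[:, 1])

    def test_single_loaded_bin_closed_form(self):
        B = 20
        depths = [0.0] * (B - 1) + [100.0]
        _, gini = cov.lorenz_gini(_track(depths))
        assert gini == pytest.approx((B - 1) / B)

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            depths = rng.gamma(2.0, 10.0, size=300)
            _, gini = cov.lorenz_gini(_track(depths))
            d = np.sort(depths)
            x = np.arange(len(d) + 1) / len(d)
            y = np.concatenate([[0.0], np.cumsum(d)]) / d.sum()
            area = sum(
                (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2
                for i in range(len(d))
            )
            assert abs(gini - (1 - 2 * area)) < 1e-9

    def test_scale_invariance_and_endpoints(self):
        rng = np.random.default_rng(10)
        depths = rng.gamma(2.0, 10.0, size=200)
        curve, gini = cov.lorenz_gini(_track(depths))
        _, gini2 = cov.lorenz_gini(_track(depths * 7.0))
        assert gini == pytest.approx(gini2)
        assert tuple(curve[0]) == (0.0, 0.0)
        assert curve[-1] == pytest.approx((1.0, 1.0))
        assert (np.diff(curve[:, 1]) >= -1e-12).all()  # non-decreasing
        assert (np.diff(np.diff(curve[:, 1])) >= -1e-9).all()  # convex

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            cov.lorenz_gini(_track([0.0] * 5))


class TestPsd:
    def test_sinusoid_peak_at_its_frequency(self):
        bin_bp, period = 250, 1000
        n = 2 ** 12
        x = (np.arange(n) + 0.5) * bin_bp
        depths = 30 + 10 * np.sin(2 * np.pi * x / period)
        psd = cov.power_spectral_density(_track(depths, bin_bp=bin_bp),
                                         segment_bins=2 ** 10)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert peak == pytest.approx(1.0 / period, rel=0.05)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(11)
        depths = np.abs(rng.normal(30, 3, 2 ** 15))
        track = _track(depths, bin_bp=500)
        psd = cov.power_spectral_density(track, segment_bins=2 ** 12)
        df = psd.frequencies[1] - psd.frequencies[0]
        integrated = float(np.sum(psd.power) * df)
        assert abs(integrated - depths.var()) / depths.var() < 0.01

    def test_too_short_track_rejected(self):
        with pytest.raises(ValidationError, match="short"):
            cov.power_spectral_density(_track([1.0]))

    def test_equal_read_scheme_rejected(self):
        t = _track([1.0] * 64, scheme="equal_read")
        with pytest.raises(ValidationError, match="fixed"):
            cov.power_spectral_density(t)


class TestSubsample:
    def test_fraction_one_identity(self):
        t = _track([10.0, 20.0, 30.0])
        out = cov.subsample_track(t, 1.0, seed=0)
        pd.testing.assert_frame_equal(out.bins, t.bins)

    def test_binomial_moments(self):
        t = _track([30.0] * 5000)
        out = cov.subsample_track(t, 0.5, seed=1)
        se = np.sqrt(30 * 0.5 * 0.5 / 5000)
        assert abs(out.depths.mean() - 15.0) < 3 * se

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValidationError, match="fraction"):
            cov.subsample_track(_track([1.0]), 1.5)

    def test_mapd_stable_under_deep_subsampling(self):
        """Low-resolution uniformity metrics barely move under 10x thinning."""
        ref = synthetic.simulate_coverage_track(
            "flat", 100_000_000, 500_000, params={"depth": 5000}, seed=12
        )
        smp = synthetic.simulate_coverage_track(
            "mda_like", 100_000_000, 500_000,
            params={"depth": 5000, "min_period_bp": 2_000_000,
                    "max_period_bp": 20_000_000, "white_sd": 0.3}, seed=13,
        )
        bins = smp.bins[["contig", "start", "end"]]
        before = cov.mapd(cov.normalized_log2(smp, ref, bins))
        thinned = cov.subsample_track(smp, 0.1, seed=2)
        ref_thin = cov.subsample_track(ref, 0.1, seed=3)
        after = cov.mapd(cov.normalized_log2(thinned, ref_thin, bins))
        assert abs(after - before) / before < 0.10


def test_pooling_preserves_shared_bins():
    tracks = [
        synthetic.simulate_coverage_track(
            "malbac_like", 1_000_000, 250, seed=s, systematic_seed=99
        )
        for s in range(3)
    ]
    pooled = cov.pool_tracks(tracks)
    assert pooled.depths.sum() == pytest.approx(
        sum(t.depths.sum() for t in tracks)
    )
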