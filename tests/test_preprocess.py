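"""Signal-cleanup contracts: trimming, denoising, baseline, COW, peaks."""

import itertools

import numpy as np
import pytest

from breathomics.core import Chromatogram
from breathomics import preprocess as pp


def make_chrom(rt, tic, sample_id="s"):
    spectra = np.tile(np.asarray(tic, dtype=float)[:, None], (1, 4))
    return Chromatogram(
        rt=np.asarray(rt, dtype=float),
        tic=np.asarray(tic, dtype=float),
        spectra=spectra,
        sample_id=sample_id,
        mz=np.arange(35, 39),
    )


class TestTrim:
    def test_boundaries_inclusive(self):
        rt = np.arange(1.0, 24.0 + 1e-9, 0.1)
        chrom = make_chrom(rt, np.ones_like(rt))
        out = pp.trim_retention_window(chrom, 1.3, 23.0)
        assert np.isclose(out.rt[0], 1.3) and np.isclose(out.rt[-1], 23.0)
        assert out.spectra.shape[0] == len(out.rt)

    def test_idempotent_inside_window(self):
        rt = np.arange(2.0, 20.0, 0.1)
        chrom = make_chrom(rt, np.ones_like(rt))
        out = pp.trim_retention_window(chrom)
        np.testing.assert_array_equal(out.rt, chrom.rt)
        np.testing.assert_array_equal(out.tic, chrom.tic)

    def test_empty_window_raises(self):
        rt = np.arange(0.0, 25.0, 0.1)
        chrom = make_chrom(rt, np.ones_like(rt))
        with pytest.raises(pp.EmptyWindowError):
            pp.trim_retention_window(chrom, 30.0, 40.0)


class TestDenoise:
    def test_smooth_signal_nearly_unchanged(self):
        rt = np.arange(0, 10, 0.01)
        tic = 10 + 5 * np.exp(-0.5 * ((rt - 5) / 0.5) ** 2)
        out = pp.denoise_wavelet(make_chrom(rt, tic))
        assert np.max(np.abs(out.tic - tic)) / np.max(tic) < 0.01

    def test_white_noise_variance_shrinks(self):
        rng = np.random.default_rng(0)
        rt = np.arange(0, 10, 0.01)
        tic = 100 + rng.normal(0, 1, len(rt))
        out = pp.denoise_wavelet(make_chrom(rt, tic))
        assert out.tic.var() < tic.var()

    @pytest.mark.parametrize("rule", ["soft", "hard", "truncate"])
    def test_noisy_peak_rmse_improves(self, rule):
        rng = np.random.default_rng(1)
        rt = np.arange(0, 10, 0.01)
        clean = 10 * np.exp(-0.5 * ((rt - 5) / 0.3) ** 2)
        noisy = clean + rng.normal(0, 1.0, len(rt))
        out = pp.denoise_wavelet(make_chrom(rt, noisy), threshold_rule=rule)
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((out.tic - clean) ** 2))
        assert rmse_after < rmse_before

    def test_short_signal_rejected(self):
        chrom = make_chrom([0.0, 0.1], [1.0, 1.0])
        with pytest.raises(ValueError):
            pp.denoise_wavelet(chrom, level=2)


class TestBaseline:
    def test_drift_only_removed(self):
        rt = np.arange(0, 20, 0.02)
        drift = 5 + 3 * np.sin(rt / 4.0)
        chrom = make_chrom(rt, drift)
        # smoothing parameter matched to the drift's frequency content
        corrected, baseline = pp.correct_baseline(chrom, lam=1e4)
        assert np.max(np.abs(corrected.tic)) < 0.01 * (drift.max() - drift.min())

    def test_flat_zero_signal(self):
        rt = np.arange(0, 10, 0.02)
        _, baseline = pp.correct_baseline(make_chrom(rt, np.zeros_like(rt)))
        assert np.max(np.abs(baseline)) < 1e-9

    def test_peak_areas_survive_drift(self):
        """Planted peaks on a drift of equal amplitude keep their areas."""
        rt = np.arange(0, 20, 0.02)
        apexes, areas, sigma = [4.0, 9.0, 14.0], [2.0, 1.5, 3.0], 0.05
        peaks = sum(
            a * np.exp(-0.5 * ((rt - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
            for mu, a in zip(apexes, areas)
        )
        amp = peaks.max()
        drift = amp / 2 * (1 + np.sin(rt / 3.0))
        # smoother matched to the drift frequency; small p because peaks
        # dominate the trace here
        corrected, _ = pp.correct_baseline(make_chrom(rt, peaks + drift),
                                           lam=1e4, p=0.01)
        for mu, a in zip(apexes, areas):
            sel = np.abs(rt - mu) < 5 * sigma
            got = np.trapezoid(corrected.tic[sel], rt[sel])
            assert abs(got - a) / a < 0.05


class TestCow:
    def test_identity_when_target_equals_reference(self):
        rng = np.random.default_rng(2)
        n = 200
        sig = np.convolve(rng.normal(0, 1, n), np.ones(9) / 9, mode="same") + 2
        chrom = make_chrom(np.arange(n) * 0.1, sig)
        aligned, path = pp.align_cow(chrom, sig, segment_len=20, slack=5)
        corr = np.corrcoef(aligned.tic, sig)[0, 1]
        assert corr > 0.999999

    def test_uniform_shift_realigned(self):
        rt = np.arange(0, 25, 0.02)
        apexes = [5.0, 10.0, 15.0, 20.0]
        sig = sum(
            np.exp(-0.5 * ((rt - mu) / 0.08) ** 2) for mu in apexes
        )
        shift = 5  # grid points
        target = np.roll(sig, shift)
        aligned, _ = pp.align_cow(make_chrom(rt, target), sig,
                                  segment_len=20, slack=7)
        for mu in apexes:
            apex = rt[np.argmax(aligned.tic * (np.abs(rt - mu) < 0.5))]
            assert abs(apex - mu) <= 0.02 + 1e-9

    def test_dp_matches_exhaustive_enumeration(self):
        """DP benefit equals brute force over all boundary placements."""
        rng = np.random.default_rng(3)
        n, seg, slack = 60, 20, 2
        ref = np.convolve(rng.normal(0, 1, n), np.ones(5) / 5, mode="same")
        target = np.convolve(rng.normal(0, 1, n), np.ones(5) / 5, mode="same")
        boundaries, benefit = pp.cow_warp_path(target, ref, seg, slack)
        nominal = [0, 20, 40, n - 1]
        best = -np.inf
        best_b = None
        ranges = [range(b - slack, b + slack + 1) for b in nominal[1:-1]]
        for combo in itertools.product(*ranges):
            cand = [0, *combo, n - 1]
            if any(cand[i + 1] - cand[i] < 2 for i in range(len(cand) - 1)):
                continue
            score = pp.cow_path_score(target, ref, cand, seg)
            if score > best:
                best, best_b = score, cand
        assert benefit == pytest.approx(best, abs=1e-10)
        assert list(boundaries) == best_b

    def test_warp_path_monotone_with_fixed_endpoints(self):
        rng = np.random.default_rng(4)
        n = 200
        ref = np.abs(np.convolve(rng.normal(0, 1, n), np.ones(7) / 7, "same"))
        tgt = np.abs(np.convolve(rng.normal(0, 1, n), np.ones(7) / 7, "same"))
        boundaries, _ = pp.cow_warp_path(tgt, ref, 20, 7)
        assert boundaries[0] == 0 and boundaries[-1] == n - 1
        assert (np.diff(boundaries) > 0).all()

    def test_bad_parameters_rejected(self):
        sig = np.ones(30)
        with pytest.raises(ValueError):
            pp.cow_warp_path(sig, sig, segment_len=40, slack=2)
        with pytest.raises(ValueError):
            pp.cow_warp_path(sig, sig, segment_len=5, slack=7)


class TestPeaks:
    def test_single_gaussian_area(self, gaussian_chromatogram):
        chrom, apexes, areas, sigma = gaussian_chromatogram
        pl = pp.detect_and_integrate_peaks(chrom, min_prominence=1.0)
        assert len(pl) == len(apexes)
        for peak, mu, a in zip(pl.peaks, apexes, areas):
            assert abs(peak.apex_rt - mu) <= chrom.grid_step
            assert abs(peak.area - a) / a < 0.02
            assert peak.start_rt < peak.apex_rt < peak.end_rt

    def test_flat_signal_yields_no_peaks(self):
        rt = np.arange(0, 10, 0.02)
        pl = pp.detect_and_integrate_peaks(
            make_chrom(rt, np.zeros_like(rt)), min_prominence=0.1
        )
        assert len(pl) == 0

    def test_two_separated_gaussians(self):
        rt = np.arange(0, 10, 0.01)
        sigma = 0.1
        tic = (
            2.0 * np.exp(-0.5 * ((rt - 3) / sigma) ** 2)
            + 1.0 * np.exp(-0.5 * ((rt - 6) / sigma) ** 2)
        ) / (sigma * np.sqrt(2 * np.pi))
        pl = pp.detect_and_integrate_peaks(make_chrom(rt, tic),
                                           min_prominence=0.5)
        assert len(pl) == 2
        assert abs(pl.peaks[0].area - 2.0) / 2.0 < 0.02
        assert abs(pl.peaks[1].area - 1.0) < 0.02

    def test_bounds_do_not_overlap(self, gaussian_chromatogram):
        chrom, *_ = gaussian_chromatogram
        pl = pp.detect_and_integrate_peaks(chrom, min_prominence=1.0)
        for a, b in zip(pl.peaks, pl.peaks[1:]):
            assert a.end_rt <= b.start_rt + 1e-9


class TestOutlierScreen:
    def test_identical_samples_unflagged(self):
        X = np.ones((10, 50))
        assert not pp.screen_outliers(X).any()

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(10, 1, size=(50, 40))
        X[7] *= 10.0
        flags = pp.screen_outliers(X, threshold_sd=5.0)
        assert flags[7]
        assert flags.sum() <= 3

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, size=(20, 10))
        assert not pp.screen_outliers(X, threshold_sd=np.inf).any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pp.screen_outliers(np.ones((2, 5)))


class TestPipelineProperties:
    def test_lockstep_preserved_and_near_idempotent(self):
        """Cleaning an already-clean, aligned signal barely changes it."""
        rt = np.arange(0.0, 25.0, 0.02)
        sigma = 0.08
        tic = sum(
            a * np.exp(-0.5 * ((rt - mu) / sigma) ** 2)
            for mu, a in [(5.0, 8.0), (12.0, 5.0), (18.0, 9.0)]
        )
        spectra = np.tile(tic[:, None], (1, 4))
        chrom = Chromatogram(rt=rt, tic=tic, spectra=spectra,
                             sample_id="clean", mz=np.arange(35, 39))
        trimmed = pp.trim_retention_window(chrom)
        out = pp.preprocess_chromatogram(chrom, reference=trimmed.tic)
        assert len(out.rt) == len(out.tic) == out.spectra.shape[0]
        rms = np.sqrt(np.mean((out.tic - trimmed.tic) ** 2))
        assert rms / np.sqrt(np.mean(trimmed.tic**2)) < 0.02
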