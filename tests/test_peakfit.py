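"""Peak picking, noise estimation/filtering, segmentation, and the
bounded pseudo-Voigt fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from voigtnmr import (
    FitConfig,
    NoiseEstimate,
    Spectrum1D,
    estimate_noise,
    fit_region,
    fit_report,
    fit_spectrum,
    integrate_peak,
    make_axis,
    noise_filter,
    pick_peaks,
    pseudo_voigt,
    pseudo_voigt_height,
    segment_regions,
    simulate_spectrum,
)


def _gauss(x, c, a, w):
    return a * np.exp(-4 * np.log(2) * ((x - c) / w) ** 2)


class TestPickPeaks:
    def test_monotone_trace_has_no_peaks(self):
        x = make_axis(0, 1, 0.01)
        assert pick_peaks(Spectrum1D(x, np.linspace(0, 1, x.size), "m")) == []

    def test_single_gaussian_found_at_center(self):
        x = make_axis(1.0, 3.0, 2.5e-4)
        s = Spectrum1D(x, _gauss(x, 2.0, 5.0, 0.01), "g")
        cands = pick_peaks(s)
        assert len(cands) == 1
        assert abs(cands[0].center - 2.0) <= 2.5e-4

    @pytest.mark.parametrize("sep,expected", [(0.005, 1), (0.03, 2)])
    def test_resolution_of_equal_pair(self, sep, expected):
        x = make_axis(1.0, 3.0, 2.5e-4)
        y = _gauss(x, 2.0 - sep / 2, 1.0, 0.01) + _gauss(x, 2.0 + sep / 2, 1.0, 0.01)
        cands = pick_peaks(Spectrum1D(x, y, "p"))
        # brute-force oracle: strict interior local maxima of the sampled sum
        brute = [i for i in range(1, x.size - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
        assert len(cands) == expected == len(brute)
        assert [c.index for c in cands] == brute

    def test_plateau_reported_once_at_center(self):
        y = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        cands = pick_peaks(Spectrum1D(np.arange(7.0), y, "pl"))
        assert len(cands) == 1 and cands[0].index == 3

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            pick_peaks(Spectrum1D(np.array([0.0, 1.0]), np.array([0.0, 1.0]), "x"))

    def test_candidate_invariants(self):
        rng = np.random.default_rng(2)
        x = make_axis(0, 1, 1e-3)
        y = _gauss(x, 0.5, 10, 0.02) + rng.normal(0, 0.3, x.size)
        for c in pick_peaks(Spectrum1D(x, y, "n")):
            assert c.left_min_index < c.index < c.right_min_index
            # net intensity is clipped to [0, height]; a noise maximum below
            # zero carries net 0 and can never pass any threshold
            assert max(c.height, 0.0) >= c.net_intensity >= 0


class TestEstimateNoise:
    def test_diff_mad_recovers_generator_sigma(self):
        rng = np.random.default_rng(0)
        x = make_axis(0, 1, 1e-4)[:10_000]
        s = Spectrum1D(x, rng.normal(0, 1.0, 10_000), "n")
        est = estimate_noise(s, method="diff_mad")
        assert 0.95 <= est.sigma <= 1.05

    def test_region_sd_recovers_generator_sigma(self):
        rng = np.random.default_rng(1)
        x = make_axis(9.0, 10.0, 5e-4)
        s = Spectrum1D(x, rng.normal(0, 2.0, x.size), "n")
        est = estimate_noise(s, method="region_sd", region=(9.5, 10.0))
        assert est.method == "region_sd"
        assert 1.9 <= est.sigma <= 2.1

    def test_missing_region_falls_back_to_diff_mad(self):
        rng = np.random.default_rng(2)
        x = make_axis(0.0, 1.0, 1e-3)
        s = Spectrum1D(x, rng.normal(0, 1.0, x.size), "n")
        est = estimate_noise(s, method="region_sd", region=(9.5, 10.0))
        assert est.method == "diff_mad"

    def test_constant_trace_is_an_error(self):
        x = make_axis(9.0, 10.0, 1e-3)
        with pytest.raises(ValueError):
            estimate_noise(Spectrum1D(x, np.zeros(x.size), "z"), method="region_sd")


class TestNoiseFilter:
    @staticmethod
    def _noisy_ten_peak_spectrum():
        rng = np.random.default_rng(7)
        x = make_axis(0.0, 5.0, 2.5e-4)
        y = rng.normal(0, 1.0, x.size)
        centers = np.linspace(0.4, 4.6, 10)
        for c in centers:
            y += _gauss(x, c, 40.0, 0.004)  # net >> 20 sigma
        return Spectrum1D(x, y, "ten"), centers

    def test_zero_threshold_keeps_everything(self):
        s, _ = self._noisy_ten_peak_spectrum()
        cands = pick_peaks(s)
        assert noise_filter(cands, NoiseEstimate(sigma=1.0), 0.0) == cands

    def test_subthreshold_candidate_removed(self):
        s, _ = self._noisy_ten_peak_spectrum()
        weak = [c for c in pick_peaks(s) if c.net_intensity < 4.0]
        assert noise_filter(weak, NoiseEstimate(sigma=1.0), 5.0) == []

    def test_true_peaks_survive_and_match_brute_force(self):
        s, centers = self._noisy_ten_peak_spectrum()
        noise = estimate_noise(s)
        cands = pick_peaks(s)
        kept = noise_filter(cands, noise, 5.0)
        # brute-force threshold scan oracle
        brute = [c for c in cands if c.net_intensity >= 5.0 * noise.sigma]
        assert kept == brute
        for c0 in centers:
            assert any(abs(c.center - c0) < 0.002 for c in kept)

    def test_subset_and_monotone_in_threshold(self):
        s, _ = self._noisy_ten_peak_spectrum()
        cands = pick_peaks(s)
        noise = NoiseEstimate(sigma=1.0)
        prev = len(cands)
        for k in (0, 1, 2, 5, 10, 50):
            kept = noise_filter(cands, noise, k)
            assert set(id(c) for c in kept) <= set(id(c) for c in cands)
            assert len(kept) <= prev
            prev = len(kept)


class TestSegmentRegions:
    def test_two_separated_peaks_two_regions(self):
        x = make_axis(0, 2, 2.5e-4)
        y = _gauss(x, 0.5, 10, 0.004) + _gauss(x, 1.5, 10, 0.004)
        s = Spectrum1D(x, y, "two")
        cands = pick_peaks(s)
        regs = segment_regions(s, cands, NoiseEstimate(sigma=0.01))
        assert len(regs) == 2
        assert all(len(r[2]) == 1 for r in regs)

    def test_overlapping_doublet_one_region(self):
        x = make_axis(0, 2, 2.5e-4)
        y = _gauss(x, 0.995, 10, 0.01) + _gauss(x, 1.005, 10, 0.01)
        s = Spectrum1D(x, y, "dbl")
        cands = pick_peaks(s)
        regs = segment_regions(s, cands, NoiseEstimate(sigma=0.01))
        assert len(regs) == 1 and len(regs[0][2]) == len(cands)

    def test_partition_property_on_many_peaks(self):
        rng = np.random.default_rng(9)
        x = make_axis(0, 10, 1e-3)
        y = rng.normal(0, 0.5, x.size)
        for c in np.linspace(0.2, 9.8, 50):
            y += _gauss(x, c, 30.0, 0.01)
        s = Spectrum1D(x, y, "fifty")
        noise = estimate_noise(s)
        cands = noise_filter(pick_peaks(s), noise, 5.0)
        regs = segment_regions(s, cands, noise)
        # pairwise disjoint spans
        spans = sorted((lo, hi) for lo, hi, _ in regs)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        # every candidate appears exactly once
        assigned = [id(c) for _, _, cc in regs for c in cc]
        assert sorted(assigned) == sorted(id(c) for c in cands)


class TestFitRegion:
    @staticmethod
    def _single_peak_region(A, w, eta, noise_sd=0.0, seed=0, mu=3.0):
        x = make_axis(mu - 0.2, mu + 0.2, 2.5e-4)
        y = pseudo_voigt(x, A, mu, w, eta)
        sigma = 1e-9
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, x.size)
            sigma = noise_sd
        s = Spectrum1D(x, y, "one")
        cands = [c for c in pick_peaks(s) if c.net_intensity > 10 * sigma]
        return s, (0, x.size - 1, cands), NoiseEstimate(sigma=sigma)

    def test_noiseless_single_peak_recovered_exactly(self):
        s, reg, noise = self._single_peak_region(1.0, 0.01, 0.7)
        fr = fit_region(s, reg, noise, FitConfig())
        p = fr.peaks[0]
        assert abs(p.A - 1.0) < 1e-4
        assert abs(p.mu - 3.0) / 3.0 < 1e-4
        assert abs(p.w - 0.01) / 0.01 < 1e-4
        assert abs(p.eta - 0.7) / 0.7 < 1e-4
        assert fr.rss < 1e-16 * fr.n_points
        assert fr.converged

    def test_noiseless_parameter_grid(self):
        for A, w, eta in itertools.product([0.3, 1.0, 3.0], [0.002, 0.005, 0.01], [0.1, 0.5, 0.9]):
            s, reg, noise = self._single_peak_region(A, w, eta)
            p = fit_region(s, reg, noise, FitConfig()).peaks[0]
            assert abs(p.A - A) / A < 1e-4
            assert abs(p.w - w) / w < 1e-4
            assert abs(p.eta - eta) / eta < 1e-4
            assert abs(p.mu - 3.0) / 3.0 < 1e-4

    def test_noisy_amplitude_recovery_and_standard_error(self):
        errs, ses = [], []
        h = pseudo_voigt_height(1.0, 0.005, 0.6)
        for seed in range(50):
            s, reg, noise = self._single_peak_region(1.0, 0.005, 0.6, noise_sd=h / 100, seed=seed)
            p = max(fit_region(s, reg, noise, FitConfig()).peaks, key=lambda q: q.A)
            errs.append(p.A - 1.0)
            ses.append(p.se_A)
        assert np.median(np.abs(errs)) < 0.01  # < 1% median relative error
        emp_sd = np.std(errs)
        assert np.median(ses) == pytest.approx(emp_sd, rel=1.0)  # within a factor 2

    def test_overlapped_pair_conserves_total_area(self):
        x = make_axis(2.8, 3.2, 2.5e-4)
        w = 0.01
        y = pseudo_voigt(x, 1.0, 3.0, w, 0.6) + pseudo_voigt(x, 0.8, 3.0 + 0.6 * w, w, 0.6)
        s = Spectrum1D(x, y, "pair")
        # supply both true components as candidates (a single maximum is picked)
        from voigtnmr.peakfit import PeakCandidate

        cands = []
        for c0 in (3.0, 3.0 + 0.6 * w):
            i = int(np.argmin(np.abs(x - c0)))
            cands.append(PeakCandidate(index=i, center=float(x[i]), height=float(y[i]),
                                       net_intensity=float(y[i]), left_min_index=0,
                                       right_min_index=x.size - 1))
        fr = fit_region(s, (0, x.size - 1, cands), NoiseEstimate(sigma=1e-9), FitConfig())
        total = sum(p.A for p in fr.peaks)
        assert total == pytest.approx(1.8, rel=5e-3)

    def test_cross_check_against_lmfit(self):
        lmfit = pytest.importorskip("lmfit")
        h = pseudo_voigt_height(1.0, 0.008, 0.4)
        s, reg, noise = self._single_peak_region(1.0, 0.008, 0.4, noise_sd=h / 200, seed=3)
        ours = max(fit_region(s, reg, noise, FitConfig()).peaks, key=lambda q: q.A)
        model = lmfit.models.PseudoVoigtModel() + lmfit.models.ConstantModel()
        params = model.make_params(amplitude=0.9, center=2.999, sigma=0.004, fraction=0.5, c=0.0)
        out = model.fit(s.intensity, params, x=s.ppm)
        assert ours.A == pytest.approx(out.params["amplitude"].value, rel=1e-2)
        assert ours.mu == pytest.approx(out.params["center"].value, abs=1e-5)
        assert ours.w == pytest.approx(out.params["fwhm"].value, rel=1e-2)
        assert ours.eta == pytest.approx(out.params["fraction"].value, abs=0.05)


class TestFitSpectrum:
    def test_flat_noise_gives_empty_table(self):
        rng = np.random.default_rng(12)
        x = make_axis(0, 2, 1e-3)
        s = Spectrum1D(x, rng.normal(0, 1.0, x.size), "flat")
        _, table = fit_spectrum(s, FitConfig(k_noise=5.0))
        assert len(table) == 0

    def test_urine_like_spectrum_recovery(self):
        from voigtnmr import urine_config

        cfg = urine_config(n_samples=1, seed=4, noise_sd=0.05, axis=(0.5, 4.5, 2.5e-4))
        cfg.peaks = [p for p in cfg.peaks if 0.6 < p.center < 4.4]
        sp, truth = simulate_spectrum(cfg, 0)
        _, table = fit_spectrum(sp)
        strong = truth[truth.snr_true >= 10]
        matched = 0
        errs = []
        for _, row in strong.iterrows():
            d = (table.center - row.center_true).abs()
            if d.min() <= 0.002:
                matched += 1
                errs.append(abs(table.area_total.iloc[int(d.idxmin())] - row.area_true) / row.area_true)
        assert matched >= 0.95 * len(strong)
        assert np.median(errs) < 0.05

    def test_bit_identical_reruns(self, small_cfg):
        sp, _ = simulate_spectrum(small_cfg, 0)
        regs1, t1 = fit_spectrum(sp)
        regs2, t2 = fit_spectrum(sp)
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)
        assert fit_report(regs1) == fit_report(regs2)


class TestFitReport:
    def test_empty_region_list(self):
        import json

        rep = fit_report([])
        assert rep["n_regions"] == 0
        json.dumps(rep)  # valid JSON

    def test_rss_matches_recomputation(self, small_cfg):
        sp, _ = simulate_spectrum(small_cfg, 1)
        regions, _ = fit_spectrum(sp)
        rep = fit_report(regions)
        for r, rblk in zip(regions, rep["regions"]):
            x = sp.ppm[r.lo_index : r.hi_index + 1]
            y = sp.intensity[r.lo_index : r.hi_index + 1]
            model = np.full_like(x, r.offset)
            for p in r.peaks:
                model = model + pseudo_voigt(x, p.A, p.mu, p.w, p.eta)
            assert rblk["rss"] == pytest.approx(float(np.sum((y - model) ** 2)), rel=1e-9, abs=1e-12)

    def test_nonconverged_region_flagged(self):
        x = make_axis(2.9, 3.1, 2.5e-4)
        y = pseudo_voigt(x, 1.0, 3.0, 0.01, 0.7)
        s = Spectrum1D(x, y, "t")
        cands = [c for c in pick_peaks(s) if c.net_intensity > 1]
        fr = fit_region(s, (0, x.size - 1, cands), NoiseEstimate(sigma=1e-9),
                        FitConfig(max_iter=1))
        rep = fit_report([fr])
        assert rep["regions"][0]["converged"] is False


class TestIntegrationWithinPipeline:
    def test_peak_table_area_column_is_truncated_integral(self, small_cfg):
        sp, _ = simulate_spectrum(small_cfg, 2)
        regions, table = fit_spectrum(sp, FitConfig(k_width=3.0))
        peaks = [p for r in regions for p in r.peaks]
        peaks.sort(key=lambda p: p.mu)
        for p, (_, row) in zip(peaks, table.iterrows()):
            assert row.area == pytest.approx(integrate_peak(p, 3.0), rel=1e-12)
            assert row.area < row.area_total
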