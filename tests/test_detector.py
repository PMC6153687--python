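import numpy as np
import pytest
from hypothesis import given, strategies as st

from hpdfinder import (
    DetectionParams,
    Spectrum,
    call_hpd_regions,
    count_peaks_in_window,
    density_profile,
    density_statistic,
    detect,
    reference_layout,
)
from hpdfinder.detector import StatProfile

from conftest import naive_density, random_poisson_spectrum


def spectrum_of(mz, lo=None, hi=None):
    mz = np.asarray(mz, dtype=float)
    rng = None if lo is None else (lo, hi)
    return Spectrum(mz=mz, intensity=np.ones(mz.size), mz_range=rng)


class TestCountPeaksInWindow:
    def test_empty_spectrum_counts_zero(self):
        spec = Spectrum(mz=np.array([]), intensity=np.array([]), mz_range=(100, 200))
        assert count_peaks_in_window(spec, 100.0, 101.0) == 0

    def test_dense_comb_full_window(self):
        spec = spectrum_of(100.0 + 0.01 * np.arange(100))
        assert count_peaks_in_window(spec, 100.0, 101.0) == 100

    def test_half_open_excludes_peak_at_hi(self):
        spec = spectrum_of([101.0])
        assert count_peaks_in_window(spec, 100.0, 101.0) == 0
        assert count_peaks_in_window(spec, 101.0, 102.0) == 1

    def test_duplicate_mz_count_separately(self):
        spec = spectrum_of([150.0, 150.0, 150.0])
        assert count_peaks_in_window(spec, 149.5, 150.5) == 3

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            count_peaks_in_window(spectrum_of([100.0]), 101.0, 100.0)


class TestDensityProfile:
    def test_empty_spectrum_all_zero(self, params):
        spec = Spectrum(mz=np.array([]), intensity=np.array([]), mz_range=(100, 110))
        prof = density_profile(spec, params)
        assert prof.centers[0] == pytest.approx(100.5)
        assert prof.centers[-1] == pytest.approx(109.5)
        assert np.all(prof.densities == 0)

    def test_grid_spacing_constant(self, params):
        spec = spectrum_of(np.linspace(200, 300, 50), lo=200, hi=300)
        prof = density_profile(spec, params)
        assert np.allclose(np.diff(prof.centers), params.step)

    def test_homogeneous_comb_interior_density(self, params):
        mz = 200.025 + 0.05 * np.arange(2000)  # exact 0.05 spacing on [200, 300]
        spec = spectrum_of(mz, lo=200, hi=300)
        prof = density_profile(spec, params)
        assert np.all(prof.densities == 20)

    def test_narrow_range_yields_empty_profile(self, params):
        spec = spectrum_of([100.1, 100.2], lo=100.0, hi=100.5)
        assert density_profile(spec, params).centers.size == 0

    @given(st.integers(0, 2**31 - 1))
    def test_matches_naive_recount(self, seed):
        params = DetectionParams()
        rng = np.random.default_rng(seed)
        spec = random_poisson_spectrum(rng)
        prof = density_profile(spec, params)
        np.testing.assert_array_equal(
            prof.densities, naive_density(spec, prof.centers, params.window_width)
        )


class TestReferenceLayout:
    def test_default_layout_arithmetic(self, params):
        lay = reference_layout(500.0, params)
        assert lay.test == (499.5, 500.5)
        assert lay.pairs[0] == ((496.5, 499.5), (500.5, 503.5))
        assert lay.pairs[1] == ((493.5, 496.5), (503.5, 506.5))

    def test_single_pair(self):
        lay = reference_layout(500.0, DetectionParams(n_pairs=1))
        assert len(lay.pairs) == 1

    @given(st.floats(200, 2000), st.integers(1, 4))
    def test_windows_tile_without_overlap_or_gaps(self, center, n_pairs):
        p = DetectionParams(n_pairs=n_pairs)
        lay = reference_layout(center, p)
        intervals = sorted([lay.test] + [w for pair in lay.pairs for w in pair])
        for (a_lo, a_hi), (b_lo, b_hi) in zip(intervals, intervals[1:]):
            assert a_hi == pytest.approx(b_lo)  # gapless => also non-overlapping


class TestDensityStatistic:
    def test_constant_profile_gives_zero_everywhere(self, flat_spectrum, params):
        stat = density_statistic(flat_spectrum, params)
        assert stat.S.size > 0
        assert np.all(stat.S == 0.0)

    def test_ten_sigma_excess_hits_100_exactly_and_is_not_called(self, flat_spectrum, params):
        # 10 extra peaks in one window against sigma' = sigma_floor = 1
        extra = np.full(10, 110.0) + np.linspace(-0.005, 0.005, 10)
        spec = Spectrum(
            mz=np.concatenate([flat_spectrum.mz, extra]),
            intensity=np.ones(flat_spectrum.n_peaks + 10),
            mz_range=flat_spectrum.mz_range,
        )
        stat = density_statistic(spec, params)
        assert stat.S.max() == 100.0
        assert call_hpd_regions(stat, spec, params) == ()

    def test_eleven_extra_peaks_cross_the_strict_threshold(self, flat_spectrum, params):
        extra = np.full(11, 110.0) + np.linspace(-0.005, 0.005, 11)
        spec = Spectrum(
            mz=np.concatenate([flat_spectrum.mz, extra]),
            intensity=np.ones(flat_spectrum.n_peaks + 11),
            mz_range=flat_spectrum.mz_range,
        )
        regions = detect(spec, params).regions
        assert len(regions) == 1
        assert regions[0].lo < 110.0 < regions[0].hi
        assert regions[0].max_S == 121.0

    def test_statistic_is_max_over_pairs(self, flat_spectrum, params):
        stat = density_statistic(flat_spectrum, params)
        d = density_profile(flat_spectrum, params).densities.astype(float)
        per_pair = ((d - stat.pair_mu) / np.maximum(stat.pair_sigma, params.sigma_floor)) ** 2
        per_pair = np.where(d - stat.pair_mu > 0, per_pair, 0.0)
        expect = np.nanmax(per_pair, axis=0)
        valid = ~np.all(np.isnan(stat.pair_mu), axis=0)
        np.testing.assert_allclose(stat.S[valid], expect[valid])

    def test_contaminated_pair_is_outvoted_by_clean_pair(self):
        # Flat comb at density 20; a dense blob sits 2 m/z right of the test
        # center, inside pair 1's right window but outside pair 2's windows.
        params = DetectionParams()
        base = 100.025 + 0.05 * np.arange(int(30 / 0.05))
        blob = np.linspace(116.8, 117.2, 400)
        test_extra = np.full(60, 115.0) + np.linspace(-0.005, 0.005, 60)
        spec = spectrum_of(np.concatenate([base, blob, test_extra]), lo=100, hi=130)
        stat = density_statistic(spec, params)
        i = int(np.argmin(np.abs(stat.centers - 115.0)))
        s1 = ((60 + 20 - stat.pair_mu[0, i]) / max(stat.pair_sigma[0, i], 1.0)) ** 2
        s2 = ((60 + 20 - stat.pair_mu[1, i]) / max(stat.pair_sigma[1, i], 1.0)) ** 2
        assert stat.pair_mu[0, i] > stat.pair_mu[1, i]  # pair 1 sees the blob
        assert s2 > s1
        assert stat.S[i] == pytest.approx(s2)

    def test_adding_peaks_in_test_window_never_decreases_s(self, params):
        rng = np.random.default_rng(42)
        spec = random_poisson_spectrum(rng, n_max=400, lo=100, hi=130)
        stat = density_statistic(spec, params)
        i = stat.centers.size // 2
        c = stat.centers[i]
        s_before = stat.S[i]
        for n_extra in (5, 15, 40):
            extra = rng.uniform(c - 0.45, c + 0.45, size=n_extra)
            spec2 = spectrum_of(np.sort(np.concatenate([spec.mz, extra])), lo=100, hi=130)
            s_after = density_statistic(spec2, params).S[i]
            assert s_after >= s_before
            s_before = s_after

    def test_one_sidedness_depleted_window_scores_zero(self, params):
        # carve peaks out of one window of an otherwise flat comb
        mz = 100.025 + 0.05 * np.arange(int(30 / 0.05))
        keep = ~((mz >= 114.5) & (mz < 115.5))
        spec = spectrum_of(mz[keep], lo=100, hi=130)
        stat = density_statistic(spec, params)
        i = int(np.argmin(np.abs(stat.centers - 115.0)))
        assert stat.S[i] == 0.0

    def test_spectrum_end_uses_only_fitting_windows(self, params):
        # on a 6 m/z range pair 2 (3.5-6.5 m/z out) never fits; pair 1 still
        # fits on one side at the edges, so S stays defined everywhere
        mz = 100.025 + 0.05 * np.arange(int(6 / 0.05))
        spec = spectrum_of(mz, lo=100, hi=106)
        stat = density_statistic(spec, params)
        assert np.all(np.isfinite(stat.S))
        assert np.all(np.isnan(stat.pair_mu[1]))  # pair 2 cannot fit anywhere
        assert np.isfinite(stat.pair_mu[0, 0]) and np.isfinite(stat.pair_mu[0, -1])
        # mid-range centers where no reference window fits fall back to S = 0
        no_ref = np.all(np.isnan(stat.pair_mu), axis=0)
        assert no_ref.any()
        assert np.all(stat.S[no_ref] == 0.0)


class TestRegionCalling:
    def _stat(self, S, start=100.5, step=0.1):
        S = np.asarray(S, dtype=float)
        centers = start + step * np.arange(S.size)
        p = DetectionParams()
        return StatProfile(centers, S, np.zeros((2, S.size)), np.zeros((2, S.size)), p)

    def test_all_below_threshold_no_regions(self, flat_spectrum, params):
        stat = self._stat(np.full(50, 100.0))
        assert call_hpd_regions(stat, flat_spectrum, params) == ()

    def test_three_center_run_is_too_narrow(self, flat_spectrum, params):
        S = np.zeros(50)
        S[10:13] = 500.0  # span 0.2 m/z < 0.3
        assert call_hpd_regions(self._stat(S), flat_spectrum, params) == ()

    def test_four_center_run_is_called_with_half_step_extension(self, flat_spectrum, params):
        S = np.zeros(50)
        S[10:15] = 500.0  # 5 centers, span 0.4
        regions = call_hpd_regions(self._stat(S), flat_spectrum, params)
        assert len(regions) == 1
        r = regions[0]
        assert r.hi - r.lo == pytest.approx(0.5)
        assert r.max_S == 500.0

    def test_regions_sorted_and_non_overlapping(self, flat_spectrum, params):
        S = np.zeros(80)
        S[10:20] = 200.0
        S[40:50] = 300.0
        regions = call_hpd_regions(self._stat(S), flat_spectrum, params)
        assert len(regions) == 2
        assert regions[0].hi <= regions[1].lo

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_poisson_spectrum(rng, n_max=500)
        p1 = DetectionParams(threshold=5.0)
        p2 = DetectionParams(threshold=20.0)
        s = density_statistic(spec, p1)
        flagged1 = set(np.flatnonzero(s.S > p1.threshold))
        flagged2 = set(np.flatnonzero(s.S > p2.threshold))
        assert flagged2 <= flagged1


class TestDetect:
    def test_empty_spectrum_yields_no_regions(self, params):
        spec = Spectrum(mz=np.array([]), intensity=np.array([]), mz_range=(100, 200))
        assert detect(spec, params).regions == ()

    def test_injected_site_recovered_once(self, params):
        from hpdfinder.simulate import FuzzySite, SimConfig, simulate_sample

        cfg = SimConfig(
            mz_range=(100.0, 300.0), baseline_rate=8.0, baseline_decay=1e6,
            fuzzy_sites=(FuzzySite(center=200.0, width=1.5, multiplier=10.0),),
            seed=3,
        )
        spec, truth, _ = simulate_sample(cfg)
        regions = detect(spec, params).regions
        t = truth.intervals[0]
        hits = [r for r in regions if r.lo < t.hi and r.hi > t.lo]
        assert len(hits) == 1
        assert len(regions) == 1

    def test_absurd_threshold_silences_detection(self, params):
        from hpdfinder.simulate import default_cohort_config, simulate_sample

        spec, _, _ = simulate_sample(default_cohort_config(seed=5))
        assert detect(spec, DetectionParams(threshold=1e6)).regions == ()


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(window_width=0), dict(step=0), dict(step=2.0), dict(n_pairs=0),
         dict(ref_width=0.5), dict(threshold=0), dict(min_region_width=0.05),
         dict(sigma_floor=0)],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectionParams(**kw)
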