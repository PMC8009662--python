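"""Polarity quantification: outline tracing, profiling, BPI, peak fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stomapolar import polarity, synth
from stomapolar.peakmodel import TWO_PI, peak_profile, wrapped_gaussian
from stomapolar.polarity import (
    BorderError, CorticalProfile, TopologyError, UndefinedBPIError,
    compute_bpi, crescent_metrics, fit_peak, sample_profile,
    select_brightest_cells, trace_outline,
)


def _disk_mask(radius, size=96, label=1):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return (((yy - c) ** 2 + (xx - c) ** 2) <= radius ** 2).astype(np.uint16) * label


class TestTraceOutline:
    def test_disk_perimeter_within_2pct(self):
        outline = trace_outline(_disk_mask(20), 1)
        assert outline.perimeter == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_two_component_region_is_topology_error(self):
        mask = _disk_mask(8)
        mask[70:80, 70:80] = 1  # second blob, same label
        with pytest.raises(TopologyError):
            trace_outline(mask, 1)

    def test_region_with_hole_is_topology_error(self):
        mask = _disk_mask(20)
        mask[44:52, 44:52] = 0
        with pytest.raises(TopologyError):
            trace_outline(mask, 1)

    def test_border_touching_region_rejected(self):
        mask = np.zeros((40, 40), np.uint16)
        mask[0:20, 10:30] = 1
        with pytest.raises(BorderError):
            trace_outline(mask, 1)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            trace_outline(_disk_mask(10), 99)

    def test_synthetic_ellipse_area_within_2pct(self, rendered_cell):
        _, mask, _, params = rendered_cell
        outline = trace_outline(mask, params.cell_id)
        a, b = params.ellipse_axes
        assert outline.area == pytest.approx(np.pi * a * b, rel=0.02)

    def test_orientation_is_positive_area(self, rendered_cell):
        _, mask, _, params = rendered_cell
        outline = trace_outline(mask, params.cell_id)
        assert polarity._signed_area(outline.boundary) > 0


class TestSampleProfile:
    def test_profile_has_63_values_per_channel(self, rendered_cell):
        image, mask, _, params = rendered_cell
        profile = sample_profile(image, trace_outline(mask, params.cell_id))
        assert len(profile.reporter) == 63
        assert len(profile.membrane) == 63

    def test_crescentless_cell_constant_within_1pct(self):
        params = synth.SynthCellParams(crescent_amplitude=0.0, noise_sd=0.0,
                                       baseline_intensity=50.0)
        image, mask, _ = synth.render_cell_image(params)
        profile = sample_profile(image, trace_outline(mask, 1))
        assert np.all(np.abs(profile.reporter - 50.0) <= 0.5)

    def test_argmax_portion_near_true_crescent_center(self, rendered_cell):
        image, mask, _, params = rendered_cell
        profile = sample_profile(image, trace_outline(mask, params.cell_id))
        argmax_angle = profile.angles[int(np.argmax(profile.reporter))]
        diff = np.angle(np.exp(1j * (argmax_angle - params.crescent_center)))
        # one portion of the *boundary arc* subtends more angle near the
        # ellipse's flat side; allow two portion-widths of angle
        assert abs(diff) <= 2 * TWO_PI / 63

    def test_band_exiting_image_is_border_error(self):
        params = synth.SynthCellParams(ellipse_axes=(25.0, 25.0), image_size=(80, 80),
                                       noise_sd=0.0)
        image, mask, _ = synth.render_cell_image(params)
        outline = trace_outline(mask, 1)
        with pytest.raises(BorderError):
            sample_profile(image, outline, band_width=60.0)

    def test_too_few_portions_rejected(self, rendered_cell):
        image, mask, _, params = rendered_cell
        with pytest.raises(ValueError):
            sample_profile(image, trace_outline(mask, params.cell_id), n_portions=4)


def _flat_profile(cell_id, level, n=63):
    return CorticalProfile(
        cell_id=cell_id, timepoint=0,
        angles=(np.arange(n) + 0.5) * TWO_PI / n,
        arc_fractions=(np.arange(n) + 0.5) / n,
        reporter=np.full(n, float(level)), membrane=np.full(n, 100.0))


class TestSelectBrightestCells:
    def test_top_10_of_15_by_mean_brightness(self):
        profiles = [_flat_profile(i, 10.0 + i) for i in range(15)]
        assert select_brightest_cells(profiles, k=10) == list(range(14, 4, -1))

    def test_fewer_cells_than_k_returns_all(self):
        profiles = [_flat_profile(i, 10.0 + i) for i in range(4)]
        assert select_brightest_cells(profiles, k=10) == [3, 2, 1, 0]

    def test_ties_broken_by_lower_cell_id(self):
        profiles = [_flat_profile(7, 50.0), _flat_profile(3, 50.0), _flat_profile(5, 20.0)]
        assert select_brightest_cells(profiles, k=2) == [3, 7]


class TestComputeBPI:
    def test_uniform_profile_is_fully_depolarized(self):
        assert compute_bpi(_flat_profile(0, 42.0)) == 1.0

    def test_single_hot_portion(self):
        values = np.zeros(63)
        values[17] = 100.0
        assert compute_bpi(values) == pytest.approx(1 / 63)

    def test_twelve_portion_crescent(self):
        # sigma chosen so the above-half-max arc of a zero-baseline bump
        # covers exactly 12 of the 63 portion midpoints (centre on a portion
        # boundary); expected count frozen from brute-force model evaluation
        delta = TWO_PI / 63
        sigma = 6 * delta / np.sqrt(2 * np.log(2))
        prof = synth.synthesize_profile(baseline=0.0, amplitude=100.0,
                                        mu=16 * delta, sigma=sigma, noise_sd=0.0)
        vmax = prof.reporter.max()
        assert int(np.sum(prof.reporter >= vmax / 2)) == 12
        assert compute_bpi(prof) == pytest.approx(12 / 63)

    def test_all_zero_profile_is_undefined(self):
        with pytest.raises(UndefinedBPIError):
            compute_bpi(np.zeros(63))

    def test_oracle_equivalence_naive_two_pass(self, rng):
        for _ in range(1000):
            values = rng.uniform(0.0, 100.0, 63)
            values[rng.integers(63)] = rng.uniform(50.0, 200.0)
            vmax = max(values)
            naive = sum(1 for v in values if v >= vmax / 2) / len(values)
            assert compute_bpi(values) == naive

    def test_monotone_sharpening_in_sigma(self):
        sigmas = np.linspace(0.05, 2.5, 40)
        bpis = [compute_bpi(synth.synthesize_profile(0.0, 100.0, np.pi, s, 0.0))
                for s in sigmas]
        assert np.all(np.diff(bpis) >= 0)

    @given(st.floats(min_value=0.01, max_value=1e4),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_scale_invariance(self, scale, seed):
        values = np.random.default_rng(seed).uniform(0.0, 50.0, 63) + 1.0
        assert compute_bpi(values * scale) == compute_bpi(values)


class TestFitPeak:
    @pytest.mark.parametrize("b,a,mu,sigma", [
        (10.0, 90.0, np.pi / 2, 0.3),
        (5.0, 40.0, 5.5, 0.15),
        (30.0, 25.0, 2.0, 0.7),
    ])
    def test_noise_free_recovery_1e4(self, b, a, mu, sigma):
        prof = synth.synthesize_profile(b, a, mu, sigma, 0.0)
        fit = fit_peak(prof)
        assert fit.converged
        assert fit.baseline == pytest.approx(b, rel=1e-4)
        assert fit.amplitude == pytest.approx(a, rel=1e-4)
        assert fit.mu == pytest.approx(mu, abs=1e-4 * TWO_PI)
        assert fit.sigma == pytest.approx(sigma, rel=1e-4)

    def test_constant_profile_degenerate(self):
        fit = fit_peak(_flat_profile(0, 50.0))
        assert fit.amplitude == 0.0
        assert fit.baseline == 50.0
        assert fit.converged and fit.degenerate
        assert fit.sigma == polarity.SENTINEL_SIGMA

    def test_noisy_sigma_recovery_median_under_10pct(self, rng):
        b, a, mu, sigma = 20.0, 80.0, 1.2, 0.35
        errs = []
        for _ in range(200):
            prof = synth.synthesize_profile(b, a, mu, sigma, 0.1 * a, rng=rng)
            errs.append(abs(fit_peak(prof).sigma - sigma) / sigma)
        assert np.median(errs) < 0.10

    def test_noisy_amplitude_bias_under_5pct(self, rng):
        b, a, mu, sigma = 20.0, 80.0, 4.0, 0.4
        amps = [fit_peak(synth.synthesize_profile(b, a, mu, sigma, 0.1 * a, rng=rng)).amplitude
                for _ in range(200)]
        assert abs(np.mean(amps) - a) / a < 0.05

    def test_scale_equivariance(self):
        prof = synth.synthesize_profile(12.0, 70.0, 2.5, 0.4, 0.0)
        scaled = CorticalProfile(0, 0, prof.angles, prof.arc_fractions,
                                 prof.reporter * 3.0, prof.membrane)
        f1, f3 = fit_peak(prof), fit_peak(scaled)
        assert f3.baseline == pytest.approx(3 * f1.baseline, rel=1e-3)
        assert f3.amplitude == pytest.approx(3 * f1.amplitude, rel=1e-3)
        assert compute_bpi(scaled) == compute_bpi(prof)


class TestCrescentMetrics:
    def test_fwhm_closed_form(self):
        fit = polarity.PeakFit(10.0, 90.0, 1.0, 0.3, 0.0, True)
        frac, height = crescent_metrics(fit)
        assert frac == pytest.approx(2 * 0.3 * np.sqrt(2 * np.log(2)) / TWO_PI, rel=1e-6)
        assert frac == pytest.approx(0.1124, abs=2e-4)
        assert height == 90.0

    def test_zero_amplitude(self):
        fit = polarity.PeakFit(10.0, 0.0, 1.0, 0.3, 0.0, True)
        assert crescent_metrics(fit) == (0.0, 0.0)

    def test_huge_sigma_caps_at_1(self):
        fit = polarity.PeakFit(10.0, 90.0, 1.0, 6.0, 0.0, True)
        assert crescent_metrics(fit)[0] == 1.0


class TestBPIBounds:
    def test_bounds_over_randomized_profiles(self, rng):
        for _ in range(1000):
            a = rng.uniform(0.0, 100.0)
            prof = synth.synthesize_profile(
                baseline=rng.uniform(0.5, 50.0), amplitude=a,
                mu=rng.uniform(0, TWO_PI), sigma=rng.uniform(0.05, 3.0),
                noise_sd=rng.uniform(0.0, 20.0), rng=rng)
            bpi = compute_bpi(prof)
            assert 1 / 63 <= bpi <= 1.0


def test_effective_amplitude_narrow_vs_wide():
    narrow = polarity.PeakFit(10.0, 50.0, 1.0, 0.3, 0.0, True)
    wide = polarity.PeakFit(0.0, 50.0, 1.0, 2.5, 0.0, True)
    assert narrow.effective_amplitude == pytest.approx(50.0, rel=1e-6)
    assert wide.effective_amplitude < 25.0  # near-flat bump, mostly baseline
    # effective curve extremes are preserved
    assert wide.effective_baseline + wide.effective_amplitude == pytest.approx(50.0)
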