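import numpy as np
import pytest
from scipy import ndimage

from semsr.evaluation import (LineProfile, extract_profile, gap_study,
                              gaussian_fit_histogram, highband_exceedance, measure_gap,
                              power_spectrum, radial_average, spectrum_study)
from semsr.images import DegenerateInputError, SEMImage
from semsr.registration import lanczos_upsample
from semsr.synth import DegradationConfig, ParticleField, degrade, render_highres


def two_peak_profile(rng, spacing_nm=3.55, n=48):
    """Random two-Gaussian-bump profile with a valley between the peaks."""
    x = np.arange(n) * spacing_nm
    c1 = rng.uniform(0.15, 0.35) * x[-1]
    c2 = rng.uniform(0.65, 0.85) * x[-1]
    a1, a2 = rng.uniform(0.6, 1.2, 2)
    s1, s2 = rng.uniform(8, 20, 2)
    y = a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2)
    y += rng.uniform(0.02, 0.08)
    return LineProfile(x, y)


def measure_gap_oracle(profile, exist_frac=0.6, width_frac=0.8, resolution_nm=1e-4):
    """Independent brute-force re-implementation: dense threshold scan over
    the linearly interpolated profile."""
    x, y = profile.positions, profile.intensities
    # sample-level local maxima (endpoints included)
    maxima = [i for i in range(len(y))
              if (i == 0 or y[i - 1] < y[i]) and (i == len(y) - 1 or y[i + 1] <= y[i])]
    if len(maxima) < 2:
        return False, None
    best = None
    for ai in range(len(maxima) - 1):
        for bi in range(ai + 1, len(maxima)):
            lo, hi = maxima[ai], maxima[bi]
            if hi - lo < 2:
                continue
            iv = lo + 1 + int(np.argmin(y[lo + 1:hi]))
            depth = min(y[lo], y[hi]) - y[iv]
            if best is None or depth > best[0]:
                best = (depth, lo, hi, iv)
    if best is None:
        return False, None
    _, lo, hi, iv = best
    ref = min(y[lo], y[hi])
    if y[iv] >= exist_frac * ref:
        return False, None
    # crossings flanking the valley lie between the two peaks; scanning just
    # that span keeps the 1e-4 nm resolution affordable
    dense_x = np.arange(x[lo], x[hi] + resolution_nm, resolution_nm)
    dense_y = np.interp(dense_x, x, y)
    iv_dense = int(round((x[iv] - x[lo]) / resolution_nm))
    thr = width_frac * ref
    above = dense_y >= thr
    left_idx = np.nonzero(above[:iv_dense + 1])[0]
    right_idx = np.nonzero(above[iv_dense:])[0]
    if len(left_idx) == 0 or len(right_idx) == 0:
        return True, None
    left = dense_x[left_idx[-1]]
    right = dense_x[iv_dense + right_idx[0]]
    return True, right - left


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        img = SEMImage(np.full((32, 32), 0.7), 7.1)
        prof = extract_profile(img, (10, 10), (150, 150))
        assert np.abs(prof.intensities - 0.7).max() < 1e-12

    def test_length_matches_geometry(self):
        img = SEMImage(np.zeros((64, 64)), 7.1)
        prof = extract_profile(img, (0, 0), (100, 0), step_nm=1.0)
        assert abs(prof.positions[-1] - 100.0) <= 1.0

    def test_axis_aligned_profile_matches_row_slice(self, rng):
        px = 7.1
        img = SEMImage(rng.uniform(size=(32, 32)), px)
        row = 10
        prof = extract_profile(img, (0.0, row * px), (31 * px, row * px), step_nm=px)
        assert np.abs(prof.intensities - img.pixels[row, :]).max() < 1e-6

    def test_out_of_bounds_endpoint_rejected(self):
        img = SEMImage(np.zeros((16, 16)), 7.1)
        with pytest.raises(ValueError):
            extract_profile(img, (0, 0), (1e4, 0))


class TestMeasureGap:
    def test_shallow_valley_no_gap(self):
        prof = LineProfile([0.0, 7.1, 14.2], [1.0, 0.9, 1.0])
        m = measure_gap(prof)
        assert not m.exists and m.width_nm is None

    def test_worked_example(self):
        # [1.0, 0.5, 1.0] at 7.1 nm pitch: 0.8-crossings at 2.84 and 11.36 nm
        prof = LineProfile([0.0, 7.1, 14.2], [1.0, 0.5, 1.0])
        m = measure_gap(prof)
        assert m.exists
        assert m.width_nm == pytest.approx(8.52, abs=1e-9)

    def test_symmetric_valley_has_symmetric_crossings(self):
        x = np.linspace(0, 100, 51)
        y = 1.0 - 0.8 * np.exp(-0.5 * ((x - 50) / 10) ** 2)
        m = measure_gap(LineProfile(x, y))
        assert m.exists
        # crossings equidistant from the valley centre at 50 nm
        left = 50 - (50 - (50 - m.width_nm / 2))
        assert abs((50 - m.width_nm / 2) + m.width_nm - (50 + m.width_nm / 2)) < 1e-9

    def test_scale_invariance(self, rng):
        prof = two_peak_profile(rng)
        m1 = measure_gap(prof)
        m2 = measure_gap(LineProfile(prof.positions, prof.intensities * 37.5))
        assert m1.exists == m2.exists
        if m1.exists and m1.width_nm is not None:
            assert m1.width_nm == pytest.approx(m2.width_nm, abs=1e-9)

    def test_reversal_invariance(self, rng):
        for seed in range(20):
            prof = two_peak_profile(np.random.default_rng(seed))
            rev = LineProfile(prof.positions[-1] - prof.positions[::-1],
                              prof.intensities[::-1])
            m1, m2 = measure_gap(prof), measure_gap(rev)
            assert m1.exists == m2.exists
            if m1.width_nm is not None and m2.width_nm is not None:
                assert m1.width_nm == pytest.approx(m2.width_nm, abs=1e-9)

    def test_single_peak_reports_reason(self):
        x = np.linspace(0, 50, 20)
        m = measure_gap(LineProfile(x, np.exp(-0.5 * ((x - 25) / 8) ** 2)))
        assert not m.exists and m.reason

    def test_agrees_with_brute_force_oracle(self):
        n_checked = 0
        for seed in range(200):
            prof = two_peak_profile(np.random.default_rng(10_000 + seed))
            got = measure_gap(prof)
            exists_o, width_o = measure_gap_oracle(prof)
            assert got.exists == exists_o
            if got.exists and got.width_nm is not None and width_o is not None:
                assert got.width_nm == pytest.approx(width_o, abs=1e-3)
                n_checked += 1
        assert n_checked > 100


@pytest.fixture(scope="module")
def triple():
    field = ParticleField(
        [(300, 500, 100), (540, 500, 100), (900, 500, 80), (1120, 500, 80)],
        (1420, 1000), seed=0,
        pairs=[(0, 1, 40.0), (2, 3, 60.0)])
    gt = render_highres(field, 7.1, texture_amplitude=0.0)
    blurred = degrade(gt, DegradationConfig(psf_sigma_nm=12.0, downsample_factor=1))
    segs = [((300, 500), (540, 500)), ((900, 500), (1120, 500))]
    return gt, blurred, segs


class TestGapStudy:
    def test_perfect_output_matches_ground_truth(self, triple):
        gt, blurred, segs = triple
        res = gap_study({"input": blurred, "output": gt, "ground_truth": gt}, segs)
        assert res.mean_abs_diff_nm["output"] == pytest.approx(0.0)
        assert res.undetected_fraction["output"] == res.undetected_fraction["ground_truth"]

    def test_blur_does_not_reduce_undetected_fraction(self, triple):
        gt, blurred, segs = triple
        res = gap_study({"input": blurred, "ground_truth": gt}, segs)
        assert res.undetected_fraction["input"] >= res.undetected_fraction["ground_truth"]

    def test_resolved_plus_unresolved_partition(self, triple):
        gt, blurred, segs = triple
        res = gap_study({"input": blurred, "ground_truth": gt}, segs)
        for cls, ws in res.widths_nm.items():
            n_resolved = sum(w is not None for w in ws)
            n_unresolved = sum(w is None for w in ws)
            assert n_resolved + n_unresolved == res.n_gaps

    def test_empty_segments_rejected(self, triple):
        gt, *_ = triple
        with pytest.raises(ValueError):
            gap_study({"ground_truth": gt}, [])

    def test_undetected_fraction_monotone_in_blur(self):
        # 100 synthetic gaps; undetected fraction must not fall as blur grows
        rng = np.random.default_rng(4)
        particles, pairs, segs = [], [], []
        for k in range(100):
            y = 150 + 400 * (k // 10)
            x = 200 + 600 * (k % 10)
            gap = rng.uniform(15, 60)
            r = 90.0
            particles += [(x, y, r), (x + 2 * r + gap, y, r)]
            pairs.append((2 * k, 2 * k + 1, gap))
            segs.append(((x, y), (x + 2 * r + gap, y)))
        field = ParticleField(particles, (6400, 4200), seed=0, pairs=pairs)
        gt = render_highres(field, 7.1, texture_amplitude=0.0)
        fractions = []
        for blur in (0.0, 8.0, 16.0, 24.0):
            img = degrade(gt, DegradationConfig(psf_sigma_nm=blur, downsample_factor=1)) \
                if blur else gt
            res = gap_study({"ground_truth": img}, segs)
            fractions.append(res.undetected_fraction["ground_truth"])
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestGaussianFit:
    def test_symmetric_data_centre(self):
        mu, _ = gaussian_fit_histogram([10.0, 20.0, 30.0])
        assert mu == pytest.approx(20.0)

    def test_monte_carlo_normal_sample(self):
        draws = np.random.default_rng(0).normal(20.0, 3.0, 10_000)
        mu, sigma = gaussian_fit_histogram(draws)
        assert mu == pytest.approx(20.0, abs=0.1)
        assert sigma == pytest.approx(3.0, abs=0.1)

    def test_bin_count_does_not_affect_fit(self):
        data = np.random.default_rng(1).normal(5, 1, 100)
        assert gaussian_fit_histogram(data, 5) == gaussian_fit_histogram(data, 50)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            gaussian_fit_histogram([3.0, 3.0, 3.0])
        with pytest.raises(DegenerateInputError):
            gaussian_fit_histogram([1.0, 2.0])


class TestPowerSpectrum:
    def test_constant_image_is_pure_dc(self):
        img = SEMImage(np.full((16, 16), 2.0), 7.1)
        spec = power_spectrum(img)
        dc = spec.magnitude[8, 8]
        assert dc == pytest.approx(2.0 * 256)
        off_dc = spec.magnitude.copy()
        off_dc[8, 8] = 0
        assert off_dc.max() < 1e-9

    def test_horizontal_sinusoid_peaks(self):
        n, k = 64, 5
        x = np.arange(n)
        img = SEMImage(np.tile(np.sin(2 * np.pi * k * x / n), (n, 1)), 7.1)
        spec = power_spectrum(img)
        mag = spec.magnitude.copy()
        centre = n // 2
        peaks = np.argsort(mag.ravel())[-2:]
        rows, cols = np.unravel_index(peaks, mag.shape)
        assert set(rows) == {centre}
        assert set(cols) == {centre - k, centre + k}

    def test_parseval(self, rng):
        img = SEMImage(rng.uniform(size=(16, 16)), 7.1)
        spec = power_spectrum(img)
        lhs = (spec.magnitude**2).sum() / img.pixels.size
        assert lhs == pytest.approx((img.pixels**2).sum(), rel=1e-9)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            power_spectrum(SEMImage(np.zeros((4, 4)), 7.1))


class TestRadialAverage:
    def test_white_noise_profile_flat(self):
        # averaged over 50 seeds the radial profile is flat within 10%
        mags = []
        for seed in range(50):
            img = SEMImage(np.random.default_rng(seed).standard_normal((64, 64)), 7.1)
            mags.append(power_spectrum(img).magnitude)
        from semsr.evaluation import Spectrum2D
        spec = power_spectrum(SEMImage(np.zeros((64, 64)) + 1, 7.1))
        avg = Spectrum2D(np.mean(mags, axis=0), spec.freq_y, spec.freq_x)
        rs = radial_average(avg, n_bins=16)
        inner = rs.magnitude[1:]  # DC bin holds the mean offset
        assert inner.max() / inner.min() < 1.1

    def test_ring_spectrum_hits_single_bin(self):
        from semsr.evaluation import Spectrum2D
        n = 64
        fy = np.fft.fftshift(np.fft.fftfreq(n, d=7.1))
        rr = np.hypot(fy[:, None], fy[None, :])
        target_r = 0.03
        mag = np.where(np.abs(rr - target_r) < 0.002, 1.0, 0.0)
        rs = radial_average(Spectrum2D(mag, fy, fy), n_bins=16)
        dominant = rs.frequency[np.argmax(rs.magnitude)]
        assert abs(dominant - target_r) < rs.frequency[1] - rs.frequency[0]

    def test_upsampled_image_depressed_above_lr_nyquist(self):
        # decimate-then-upsample loses energy above the low-resolution Nyquist
        field_particles = [(x * 150.0 + 100, y * 150.0 + 100, 30.0)
                           for x in range(8) for y in range(8)]
        field = ParticleField(field_particles, (1420, 1420), seed=0)
        gt = render_highres(field, 7.1, texture_amplitude=0.0)
        lr = degrade(gt, DegradationConfig(psf_sigma_nm=8.0, downsample_factor=2))
        up = lanczos_upsample(lr, 2)
        spectra = spectrum_study({"gt": [gt], "up": [up]}, n_bins=32)
        lr_nyq = 1.0 / (2 * 14.2)
        mask = spectra["gt"].frequency > lr_nyq
        assert np.all(spectra["up"].magnitude[mask] <= spectra["gt"].magnitude[mask])

    def test_invalid_bins(self):
        spec = power_spectrum(SEMImage(np.random.default_rng(0).uniform(size=(16, 16)), 7.1))
        with pytest.raises(ValueError):
            radial_average(spec, n_bins=1)


class TestSpectrumStudy:
    def test_single_image_equals_radial_of_power_spectrum(self, rng):
        img = SEMImage(rng.uniform(size=(32, 32)), 7.1)
        direct = radial_average(power_spectrum(img), 16)
        via_study = spectrum_study({"a": [img]}, 16)["a"]
        assert np.allclose(direct.magnitude, via_study.magnitude)

    def test_copies_average_to_same_result(self, rng):
        img = SEMImage(rng.uniform(size=(32, 32)), 7.1)
        one = spectrum_study({"a": [img]}, 16)["a"]
        many = spectrum_study({"a": [img, img, img]}, 16)["a"]
        assert np.allclose(one.magnitude, many.magnitude)

    def test_shape_mismatch_rejected(self, rng):
        a = SEMImage(rng.uniform(size=(32, 32)), 7.1)
        b = SEMImage(rng.uniform(size=(16, 16)), 7.1)
        with pytest.raises(ValueError):
            spectrum_study({"a": [a, b]})

    def test_highband_exceedance_bounds(self, rng):
        img = SEMImage(rng.uniform(size=(32, 32)), 7.1)
        rs = spectrum_study({"a": [img]}, 16)["a"]
        assert highband_exceedance(rs, rs, cutoff_cycles_per_nm=0.01) == 0.0
        with pytest.raises(ValueError):
            highband_exceedance(rs, rs, cutoff_cycles_per_nm=1e9)
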