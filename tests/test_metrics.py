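"""Image-quality metrics: SNR/CNR, bar MTF, FSC/FIRE, ring residual."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter, gaussian_filter1d

import helict
from helict.errors import MetricError
from helict.metrics import (
    FscCurve,
    MtfGroupRoi,
    RoiPair,
    cnr,
    cutoff_to_linewidth,
    fsc,
    mtf_bar_pattern,
    ring_residual,
    snr,
    split_half,
)


def box_rois(shape, fg_box, bg_box):
    fg = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    fg[fg_box[0] : fg_box[1], fg_box[2] : fg_box[3]] = True
    bg[bg_box[0] : bg_box[1], bg_box[2] : bg_box[3]] = True
    return RoiPair(foreground=fg, background=bg)


class TestSnrCnr:
    def test_definitions_on_constructed_rois(self):
        img = np.zeros((20, 20))
        rois = box_rois(img.shape, (0, 5, 0, 10), (10, 15, 0, 10))
        img[rois.foreground] = 10.0
        img[rois.background] = np.tile([1.0, -1.0, 1.0, -1.0, 1.0], 10)  # std 1...
        bg_std = img[rois.background].std()
        assert snr(img, rois) == pytest.approx(10.0 / bg_std)
        assert cnr(img, rois) == pytest.approx(
            abs(10.0 - img[rois.background].mean()) / bg_std
        )

    def test_hand_computed_five_by_five(self):
        """Values match a hand calculation on a printed 5x5 array."""
        img = np.array(
            [
                [4.0, 4.0, 4.0, 4.0, 4.0],
                [4.0, 9.0, 9.0, 9.0, 4.0],
                [4.0, 9.0, 9.0, 9.0, 4.0],
                [4.0, 9.0, 9.0, 9.0, 4.0],
                [4.0, 4.0, 4.0, 4.0, 4.0],
            ]
        )
        img = np.kron(img, np.ones((3, 3)))  # >= 25 samples per ROI
        noise = np.zeros_like(img)
        noise[0, 0::3] = 0.3
        noise[-1, 1::3] = -0.3
        img = img + noise
        fg = np.kron(
            np.pad(np.ones((3, 3), bool), 1, constant_values=False),
            np.ones((3, 3), bool),
        )
        bg = ~fg
        rois = RoiPair(foreground=fg, background=bg)
        # hand numbers: fg mean 9, bg mean 4 + tiny, bg std from 10 spikes
        bg_vals = img[bg]
        assert snr(img, rois) == pytest.approx(9.0 / bg_vals.std())
        assert cnr(img, rois) == pytest.approx((9.0 - bg_vals.mean()) / bg_vals.std())

    def test_pure_noise_snr_matches_distribution(self, rng):
        img = 5.0 + rng.standard_normal((200, 200))
        rois = box_rois(img.shape, (0, 80, 0, 200), (100, 180, 0, 200))
        assert snr(img, rois) == pytest.approx(5.0, rel=0.05)

    def test_constant_offset_shifts_snr(self, rng):
        img = rng.standard_normal((40, 40))
        rois = box_rois(img.shape, (0, 10, 0, 40), (20, 30, 0, 40))
        base = snr(img, rois)
        shifted = snr(img + 3.0, rois)
        bg_std = img[rois.background].std()
        assert shifted - base == pytest.approx(3.0 / bg_std, rel=1e-9)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_cnr_invariant_under_affine_maps(self, a, b):
        rng = np.random.default_rng(7)
        img = rng.standard_normal((30, 30))
        rois = box_rois(img.shape, (0, 10, 0, 30), (15, 25, 0, 30))
        assert cnr(a * img + b, rois) == pytest.approx(cnr(img, rois), rel=1e-6)

    def test_overlapping_rois_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(MetricError):
            snr(img, box_rois(img.shape, (0, 6, 0, 10), (5, 10, 0, 10)))

    def test_zero_noise_undefined(self):
        img = np.ones((20, 20))
        with pytest.raises(MetricError):
            snr(img, box_rois(img.shape, (0, 5, 0, 20), (10, 15, 0, 20)))


def square_wave_modulations(freqs_lp_mm, sigma_mm, n_harmonics=49):
    """Closed-form peak-trough modulation of a Gaussian-blurred 50%-duty
    square wave, normalized so the unblurred limit is 1."""
    out = []
    for f in freqs_lp_mm:
        h = 0.0
        for n in range(1, n_harmonics + 1, 2):
            h += ((-1) ** ((n - 1) // 2) / n) * math.exp(
                -2 * math.pi**2 * sigma_mm**2 * n**2 * f**2
            )
        out.append(4.0 / math.pi * h)
    return np.array(out)


def blurred_bar_group(freq_lp_mm, pixel_mm, sigma_px, n_rows=8, n_periods=6):
    """Sampled bar group with bar centres on pixel centres, supersampled and
    Gaussian-blurred before downsampling."""
    m = 1.0 / (2.0 * freq_lp_mm) / pixel_mm  # half-period in pixels
    fine = 16
    n_px = int(round(2 * m * n_periods))
    x = (np.arange(n_px * fine) + 0.5) / fine  # pixel units
    # bars centred on integer+0.5 pixel positions
    phase = np.floor((x - 0.5 + m / 2) / m).astype(int)
    wave = (phase % 2 == 0).astype(float)
    wave = gaussian_filter1d(wave, sigma_px * fine, mode="wrap")
    profile = wave[fine // 2 :: fine][:n_px]
    return np.tile(profile, (n_rows, 1))


class TestMtf:
    pixel = 0.02
    sigma_px = 2.2

    def groups(self, freqs):
        return [
            MtfGroupRoi(freq_lp_mm=f, roi=blurred_bar_group(f, self.pixel, self.sigma_px))
            for f in freqs
        ]

    def test_perfect_bars_have_unit_mtf_everywhere(self):
        gs = [
            MtfGroupRoi(freq_lp_mm=f, roi=blurred_bar_group(f, self.pixel, 1e-6))
            for f in (2.5, 4.0, 6.25)
        ]
        curve = mtf_bar_pattern(gs, pixel_mm=self.pixel)
        np.testing.assert_allclose(curve.modulation, 1.0, atol=0.02)
        assert curve.cutoff_lp_mm is None and not curve.in_range

    def test_gaussian_blur_cutoff_matches_closed_form(self):
        """Measured 10% cutoff within 5% of the analytic square-wave MTF of
        the known Gaussian blur."""
        freqs = [2.5, 4.0, 5.0, 6.25, 8.333, 12.5]
        curve = mtf_bar_pattern(self.groups(freqs), pixel_mm=self.pixel)
        pred = square_wave_modulations(freqs, self.sigma_px * self.pixel)
        pred = pred / pred[0]
        i = np.nonzero(pred < 0.10)[0][0]
        f_pred = freqs[i - 1] + (pred[i - 1] - 0.10) * (freqs[i] - freqs[i - 1]) / (
            pred[i - 1] - pred[i]
        )
        assert curve.cutoff_lp_mm == pytest.approx(f_pred, rel=0.05)

    def test_beyond_nyquist_excluded_with_warning(self):
        freqs = [2.5, 4.0, 6.25, 30.0]  # Nyquist is 25 at 20 um pixels
        gs = self.groups(freqs[:3]) + [
            MtfGroupRoi(freq_lp_mm=30.0, roi=np.ones((4, 16)))
        ]
        with pytest.warns(UserWarning, match="Nyquist"):
            curve = mtf_bar_pattern(gs, pixel_mm=self.pixel)
        assert curve.excluded == [30.0]

    def test_too_few_groups_rejected(self):
        with pytest.raises(MetricError):
            mtf_bar_pattern(self.groups([2.5, 4.0]), pixel_mm=self.pixel)


class TestCutoffToLinewidth:
    @pytest.mark.parametrize(
        "f, lw", [(17.2, 29.07), (17.6, 28.41), (10.0, 50.0)]
    )
    def test_printed_values(self, f, lw):
        assert cutoff_to_linewidth(f) == pytest.approx(lw, abs=0.005)


class TestFsc:
    def test_self_correlation_is_one_in_every_shell(self, rng):
        vol = gaussian_filter(rng.standard_normal((32, 32, 32)), 2.0)
        with pytest.warns(UserWarning):
            curve = fsc(vol, vol)
        np.testing.assert_allclose(curve.raw, 1.0, atol=1e-9)

    def test_independent_noise_decorrelates(self, rng):
        a = rng.standard_normal((32, 32, 32))
        b = rng.standard_normal((32, 32, 32))
        curve = fsc(a, b)
        n = 32
        for s in range(2, n // 2):
            n_shell = 4 * np.pi * s**2 / 2  # Hermitian half
            assert abs(curve.raw[s]) < 3.0 / math.sqrt(n_shell)

    def test_known_snr_matches_closed_form(self, rng):
        """FSC of signal-plus-independent-noise pairs matches
        SNR/(SNR+1) per shell within 0.05."""
        n = 64
        sig = gaussian_filter(rng.standard_normal((n, n, n)), 1.5) * 8.0
        a = sig + rng.standard_normal((n, n, n))
        b = sig + rng.standard_normal((n, n, n))
        curve = fsc(a, b)
        fs = np.fft.fftn(sig)
        r = np.sqrt(
            np.add.outer(
                np.add.outer(np.fft.fftfreq(n) ** 2, np.fft.fftfreq(n) ** 2),
                np.fft.fftfreq(n) ** 2,
            )
        )
        shell = np.minimum((r * n).round().astype(int), n // 2)
        p_sig = np.bincount(shell.ravel(), np.abs(fs).ravel() ** 2, n // 2 + 1)
        counts = np.bincount(shell.ravel(), minlength=n // 2 + 1)
        snr_shell = p_sig / counts / n**3  # noise power per coeff = n^3
        expected = snr_shell / (snr_shell + 1.0)
        dev = np.abs(curve.raw[3 : n // 2 - 2] - expected[3 : n // 2 - 2])
        assert dev.max() < 0.05

    def test_fire_never_below_nyquist_floor(self, rng):
        a = rng.standard_normal((24, 24, 24))
        b = rng.standard_normal((24, 24, 24))
        curve = fsc(a, b, voxel_mm=0.013)
        assert curve.fire_voxels >= 2.0
        assert curve.fire_mm == pytest.approx(curve.fire_voxels * 0.013)

    def test_symmetric_in_arguments(self, rng):
        a = gaussian_filter(rng.standard_normal((16, 16, 16)), 1.0)
        b = a + 0.5 * rng.standard_normal((16, 16, 16))
        np.testing.assert_allclose(fsc(a, b).raw, fsc(b, a).raw, atol=1e-12)


class TestSplitHalf:
    def _stack(self, n=8):
        geom = helict.ScanGeometry(
            mode="standard", pixel_mm=0.013, n_rows=2, n_cols=6, n_proj=2 * n
        )
        frames = np.arange(n * 12, dtype=float).reshape(n, 2, 6)
        return helict.ProjectionStack(frames=frames, role="corrected", geometry=geom)

    def test_interleaved_split(self):
        stack = self._stack(8)
        odd, even = split_half(stack)
        assert odd.n_frames == even.n_frames == 4
        np.testing.assert_array_equal(odd.frames, stack.frames[0::2])
        np.testing.assert_array_equal(even.frames, stack.frames[1::2])

    def test_reunion_reproduces_original(self):
        stack = self._stack(8)
        odd, even = split_half(stack)
        rebuilt = np.empty_like(stack.frames)
        rebuilt[0::2] = odd.frames
        rebuilt[1::2] = even.frames
        np.testing.assert_array_equal(rebuilt, stack.frames)

    def test_angles_re_spaced_with_offset(self):
        stack = self._stack(8)
        odd, even = split_half(stack)
        step = 2 * np.pi / stack.geometry.n_proj
        np.testing.assert_allclose(np.diff(odd.angles()), 2 * step)
        np.testing.assert_allclose(even.angles()[0], stack.angles()[1])


class TestRingResidual:
    def _radial(self, n=128, fn=None):
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - c, xx - c)
        return rr, (fn(rr) if fn else np.zeros((n, n)))

    def test_smooth_phantom_scores_near_zero(self):
        rr, img = self._radial(fn=lambda r: 1.0 / (1.0 + (r / 30.0) ** 2))
        assert ring_residual(img) < 0.01 * np.ptp(img)

    def test_sinusoidal_ring_amplitude_recovered(self):
        amp, period = 0.5, 6.0
        rr, img = self._radial(fn=lambda r: amp * np.sin(2 * np.pi * r / period))
        assert ring_residual(img) == pytest.approx(amp / math.sqrt(2), rel=0.2)

    def test_invariant_under_rotation(self, rng):
        from scipy.ndimage import rotate

        rr, img = self._radial(
            fn=lambda r: 0.3 * np.sin(2 * np.pi * r / 7.0) + 1.0 / (1 + r / 20)
        )
        rot = rotate(img, 37.0, reshape=False, order=3, mode="nearest")
        a = ring_residual(img, support_radius=40)
        b = ring_residual(rot, support_radius=40)
        assert b == pytest.approx(a, rel=0.05)
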