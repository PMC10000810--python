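"""Quantitative image-quality metrics.

Signal/contrast-to-noise from foreground/background regions of interest,
bar-pattern modulation transfer with the 10% cutoff, Fourier shell
correlation between half-dataset reconstructions with the 1/7-threshold
resolution (FIRE), and a polar-domain ring-residual score that turns the
qualitative ring-artifact comparison into a number.

Definitions (fg = region containing the object, bg = object-free region):

    SNR = mean(fg) / std(bg)              CNR = |mean(fg) - mean(bg)| / std(bg)

Whether the noise term should come from the background or the foreground is
a convention; both are computed and the background-noise variant is the
default (see ``snr(..., noise_roi=...)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .errors import GeometryError, MetricError
from .geometry import ProjectionStack

__all__ = [
    "RoiPair",
    "snr",
    "cnr",
    "MtfGroupRoi",
    "MtfCurve",
    "mtf_bar_pattern",
    "cutoff_to_linewidth",
    "FscCurve",
    "fsc",
    "split_half",
    "ring_residual",
]

MIN_ROI_SAMPLES = 25


@dataclass
class RoiPair:
    """Disjoint foreground/background pixel sets, as boolean masks or index
    tuples, each containing at least 25 samples."""

    foreground: np.ndarray
    background: np.ndarray

    def select(self, image: np.ndarray):
        img = np.asarray(image)
        fg = img[self.foreground]
        bg = img[self.background]
        if fg.size < MIN_ROI_SAMPLES or bg.size < MIN_ROI_SAMPLES:
            raise MetricError(
                f"ROIs need >= {MIN_ROI_SAMPLES} samples, got {fg.size}/{bg.size}"
            )
        fg_mask = np.zeros(img.shape, dtype=bool)
        bg_mask = np.zeros(img.shape, dtype=bool)
        fg_mask[self.foreground] = True
        bg_mask[self.background] = True
        if (fg_mask & bg_mask).any():
            raise MetricError("foreground and background ROIs overlap")
        return fg.astype(np.float64), bg.astype(np.float64)


def snr(image: np.ndarray, rois: RoiPair, noise_roi: str = "background") -> float:
    """Signal-to-noise ratio: foreground mean over ROI noise.

    ``noise_roi`` selects where the standard deviation is taken
    (``"background"``, the default convention, or ``"foreground"``).
    """
    fg, bg = rois.select(image)
    noise = bg.std(ddof=0) if noise_roi == "background" else fg.std(ddof=0)
    if noise == 0:
        raise MetricError("zero noise standard deviation: SNR undefined")
    return float(fg.mean() / noise)


def cnr(image: np.ndarray, rois: RoiPair) -> float:
    """Contrast-to-noise ratio |mean(fg) - mean(bg)| / std(bg)."""
    fg, bg = rois.select(image)
    noise = bg.std(ddof=0)
    if noise == 0:
        raise MetricError("zero background standard deviation: CNR undefined")
    return float(abs(fg.mean() - bg.mean()) / noise)


# ---------------------------------------------------------------------- #
# bar-pattern MTF
# ---------------------------------------------------------------------- #
@dataclass
class MtfGroupRoi:
    """One bar group: its spatial frequency and the image patch containing
    several bar periods; bars modulate along ``axis``."""

    freq_lp_mm: float
    roi: np.ndarray
    axis: int = 1


@dataclass
class MtfCurve:
    freqs_lp_mm: np.ndarray
    modulation: np.ndarray  # normalized to the lowest-frequency group
    cutoff_lp_mm: Optional[float]
    threshold: float
    excluded: list = field(default_factory=list)

    @property
    def in_range(self) -> bool:
        return self.cutoff_lp_mm is not None


def mtf_bar_pattern(
    groups: Sequence[MtfGroupRoi],
    pixel_mm: float,
    threshold: float = 0.10,
) -> MtfCurve:
    """Square-wave modulation transfer from bar-group patches.

    Per group, the profile is the patch mean across the bar direction and the
    modulation is ``(P - T) / (P + T)`` from the profile's peak and trough
    values, normalized to the lowest-frequency group.  The cutoff frequency
    is the linear interpolation of the crossing of ``threshold`` (10%
    default: the smallest resolvable object).  Groups beyond the sampling
    Nyquist frequency are excluded with a warning; if the curve never
    crosses the threshold the cutoff is flagged out of range (``None``).
    """
    if len(groups) < 3:
        raise MetricError("need at least 3 bar groups spanning the cutoff")
    nyquist = 1.0 / (2.0 * pixel_mm)
    freqs, mods, excluded = [], [], []
    for g in sorted(groups, key=lambda g: g.freq_lp_mm):
        if g.freq_lp_mm <= 0:
            raise MetricError("bar frequencies must be positive")
        if g.freq_lp_mm > nyquist:
            excluded.append(g.freq_lp_mm)
            continue
        roi = np.asarray(g.roi, dtype=np.float64)
        profile = roi.mean(axis=0 if g.axis == 1 else 1)
        p, t = float(profile.max()), float(profile.min())
        if p + t == 0:
            raise MetricError("degenerate bar profile (P + T = 0)")
        freqs.append(g.freq_lp_mm)
        mods.append((p - t) / (p + t))
    if excluded:
        warnings.warn(
            f"{len(excluded)} bar groups beyond the Nyquist frequency "
            f"({nyquist:.2f} Lps/mm) excluded",
            stacklevel=2,
        )
    freqs = np.asarray(freqs)
    mods = np.asarray(mods)
    if mods.size < 3:
        raise MetricError("fewer than 3 usable bar groups")
    mods = mods / mods[0]

    cutoff = None
    below = np.nonzero(mods < threshold)[0]
    if below.size and below[0] > 0:
        i = below[0]
        f0, f1 = freqs[i - 1], freqs[i]
        m0, m1 = mods[i - 1], mods[i]
        cutoff = float(f0 + (m0 - threshold) * (f1 - f0) / (m0 - m1))
    return MtfCurve(
        freqs_lp_mm=freqs,
        modulation=mods,
        cutoff_lp_mm=cutoff,
        threshold=threshold,
        excluded=excluded,
    )


def cutoff_to_linewidth(freq_lp_mm: float) -> float:
    """Smallest resolvable linewidth in micrometres: ``1000 / (2 f)`` for a
    cutoff frequency in line pairs per mm (17.2 Lps/mm -> 29.07 um)."""
    if freq_lp_mm <= 0:
        raise MetricError("cutoff frequency must be positive")
    return 1000.0 / (2.0 * freq_lp_mm)


# ---------------------------------------------------------------------- #
# Fourier shell correlation
# ---------------------------------------------------------------------- #
@dataclass
class FscCurve:
    """FSC versus spatial frequency plus the threshold resolution.

    ``freqs`` are shell centre frequencies in cycles/voxel; ``fire_voxels``
    is the reciprocal of the (smoothed-curve) threshold crossing, floored at
    2 voxels (Nyquist); multiply by the voxel size for physical length
    (``fire_mm``)."""

    freqs: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    threshold: float
    fire_voxels: float
    voxel_mm: float = 1.0
    crossed: bool = True

    @property
    def fire_mm(self) -> float:
        return self.fire_voxels * self.voxel_mm


def fsc(
    volume_a: np.ndarray,
    volume_b: np.ndarray,
    smooth_window: int = 5,
    threshold: float = 1.0 / 7.0,
    voxel_mm: float = 1.0,
) -> FscCurve:
    """Fourier shell correlation between two reconstructions of one object.

        FSC(s) = Re sum_shell F_a conj(F_b)
                 / sqrt( sum_shell |F_a|^2 * sum_shell |F_b|^2 )

    over unit-width shells of the 3D DFT.  The curve is smoothed by a
    centred moving average (``smooth_window`` shells) and the Fourier image
    resolution (FIRE) is the reciprocal of the frequency where the smoothed
    curve first crosses ``threshold`` (1/7 by default), in voxels (never
    below the 2-voxel Nyquist floor).
    """
    a = np.asarray(volume_a, dtype=np.float64)
    b = np.asarray(volume_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 3:
        raise GeometryError("volumes must be 3D and share a shape")
    if a is volume_b or volume_a is volume_b:
        warnings.warn("FSC of a volume with itself is trivially 1", stacklevel=2)

    fa = sp_fft.fftn(a)
    fb = sp_fft.fftn(b)
    freq_axes = [sp_fft.fftfreq(n) for n in a.shape]
    r = np.sqrt(
        freq_axes[0][:, None, None] ** 2
        + freq_axes[1][None, :, None] ** 2
        + freq_axes[2][None, None, :] ** 2
    )
    n_shell = min(a.shape) // 2 + 1
    shell = np.minimum((r * min(a.shape)).round().astype(int), n_shell)

    cross = np.bincount(shell.ravel(), (fa * fb.conj()).real.ravel(), n_shell + 1)
    pa = np.bincount(shell.ravel(), np.abs(fa).ravel() ** 2, n_shell + 1)
    pb = np.bincount(shell.ravel(), np.abs(fb).ravel() ** 2, n_shell + 1)
    cross, pa, pb = cross[:n_shell], pa[:n_shell], pb[:n_shell]
    denom = np.sqrt(pa * pb)
    raw = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    raw = np.clip(raw, -1.0, 1.0)

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(
            np.pad(raw, smooth_window // 2, mode="edge"), kernel, mode="valid"
        )[: raw.size]
    else:
        smoothed = raw.copy()

    freqs = np.arange(n_shell) / min(a.shape)  # cycles per voxel
    crossed = False
    fire = 2.0  # Nyquist floor
    below = np.nonzero(smoothed[1:] < threshold)[0]
    if below.size:
        i = below[0] + 1
        f0, f1 = freqs[i - 1], freqs[i]
        c0, c1 = smoothed[i - 1], smoothed[i]
        f_star = f0 if c0 == c1 else f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
        if f_star > 0:
            fire = max(1.0 / f_star, 2.0)
            crossed = True
    return FscCurve(
        freqs=freqs,
        raw=raw,
        smoothed=smoothed,
        threshold=threshold,
        fire_voxels=fire,
        voxel_mm=voxel_mm,
        crossed=crossed,
    )


def split_half(stack: ProjectionStack) -> tuple[ProjectionStack, ProjectionStack]:
    """Split a stack into interleaved odd/even projection halves.

    Counting projections from 1 as acquired, the first returned stack holds
    the odd ones (0-based indices 0, 2, 4, ...) and the second the even
    ones; angular order is preserved and both halves carry a re-spaced
    geometry (the even half with a constant angle offset), so each can be
    reconstructed independently for FSC.
    """
    if stack.n_frames < 2:
        raise GeometryError("need at least 2 projections to split")
    if stack.n_frames % 2:
        raise GeometryError("odd/even split needs an even projection count")
    geom = stack.geometry.replace(n_proj=stack.geometry.n_proj // 2)
    step = 2.0 * np.pi / stack.geometry.n_proj
    first = ProjectionStack(
        frames=stack.frames[0::2],
        role=stack.role,
        geometry=geom,
        mask=None if stack.mask is None else stack.mask[0::2],
        angle_offset=stack.angle_offset,
    )
    second = ProjectionStack(
        frames=stack.frames[1::2],
        role=stack.role,
        geometry=geom,
        mask=None if stack.mask is None else stack.mask[1::2],
        angle_offset=stack.angle_offset + step,
    )
    return first, second


# ---------------------------------------------------------------------- #
# ring residual
# ---------------------------------------------------------------------- #
def ring_residual(
    slice2d: np.ndarray,
    center: Optional[tuple] = None,
    support_radius: Optional[float] = None,
    r_min: int = 4,
    n_theta: int = 360,
    radial_sigma: float = 4.0,
) -> float:
    """Ring power of one reconstructed slice (rotation-invariant).

    The slice is resampled to polar coordinates about ``center`` (default:
    the FBP rotation centre ``(N-1)/2``); rings are azimuthally coherent, so
    the azimuthal mean profile is computed, its smooth radial trend (Gaussian,
    ``radial_sigma`` pixels) subtracted, and the RMS of the residual over
    radii ``[r_min, support_radius]`` returned.  A smooth phantom scores near
    zero; a sinusoidal radial ripple of amplitude A scores ~A/sqrt(2).
    """
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise GeometryError("ring_residual expects a 2D slice")
    cy, cx = (
        ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
        if center is None
        else center
    )
    if support_radius is None:
        support_radius = 0.45 * min(img.shape)
    r_max = int(math.floor(support_radius))
    if r_max <= r_min + 4:
        raise MetricError("support radius too small for a ring estimate")
    radii = np.arange(0, r_max + 1, dtype=np.float64)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    yy = cy + radii[:, None] * np.sin(thetas)[None, :]
    xx = cx + radii[:, None] * np.cos(thetas)[None, :]
    polar = ndimage.map_coordinates(img, [yy, xx], order=1, mode="nearest")
    profile = polar.mean(axis=1)
    trend = ndimage.gaussian_filter1d(profile, radial_sigma, mode="nearest")
    resid = (profile - trend)[r_min:]
    return float(np.sqrt(np.mean(resid**2)))
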