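"""Sinogram-domain ring/stripe removal baselines.

Two classic post-hoc ring suppressors the helical conversion is benchmarked
against.  Both operate on a single ``[angle, column]`` sinogram, where a
fixed-pattern detector error shows up as a vertical stripe (a ring in the
reconstruction).

* ``raven_filter`` — low-pass Fourier filtering: a detector stripe lives on
  the zero-angular-frequency line of the 2D spectrum; a Gaussian notch
  attenuates the high column frequencies of that line (sigmas 10 and 1 by
  default) while leaving DC untouched, so the global mean is preserved.
* ``sorting_stripe_filter`` — sorting-based stripe removal: intensities of
  each column are sorted along the angle axis, a horizontal median filter
  (window 10) removes the stripe from the sorted image, and the sort is
  inverted.  An optional SNR threshold (recommended 1.1-3.0) detects large
  or unresponsive (dead-column) stripes and replaces them by linear
  interpolation across columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .errors import GeometryError

__all__ = ["StripeFilterParams", "raven_filter", "sorting_stripe_filter"]


@dataclass
class StripeFilterParams:
    method: str = "raven"
    u_sigma: float = 10.0  # column-frequency width (Raven)
    v_sigma: float = 1.0  # angular-frequency width (Raven)
    window: int = 10  # median window, pixels (sorting)
    snr: Optional[float] = None  # stripe-detection gate (sorting)

    def __post_init__(self) -> None:
        if self.method not in ("raven", "sorting"):
            raise GeometryError(f"unknown method {self.method!r}")
        if self.u_sigma <= 0 or self.v_sigma <= 0:
            raise GeometryError("sigmas must be positive")
        w = int(self.window)
        if w < 3:
            w = 3
        if w % 2 == 0:
            w += 1  # median windows must be odd
        self.window = w
        if self.snr is not None and not 1.1 <= self.snr <= 3.0:
            warnings.warn(
                f"snr={self.snr} outside the recommended 1.1-3.0 band",
                stacklevel=2,
            )


def _as_sino(sinogram) -> np.ndarray:
    s = np.asarray(sinogram, dtype=np.float64)
    if s.ndim != 2:
        raise GeometryError("sinogram must be 2D [angle, column]")
    return s


def raven_filter(sinogram, params: Optional[StripeFilterParams] = None) -> np.ndarray:
    params = params or StripeFilterParams(method="raven")
    sino = _as_sino(sinogram)
    n_ang, n_det = sino.shape
    u = sp_fft.fftfreq(n_det) * n_det  # column-frequency index
    v = sp_fft.fftfreq(n_ang) * n_ang  # angular-frequency index
    # attenuate high-u content of the (near-)zero angular-frequency band only
    notch = np.exp(-(v[:, None] ** 2) / (2 * params.v_sigma**2)) * (
        1.0 - np.exp(-(u[None, :] ** 2) / (2 * params.u_sigma**2))
    )
    h = 1.0 - notch  # h(0, 0) = 1: global mean preserved
    return sp_fft.ifft2(sp_fft.fft2(sino) * h).real


def _detect_stripes(profile: np.ndarray, snr: float) -> np.ndarray:
    """Flag columns whose response deviates by more than ``snr`` noise units
    from a smooth baseline (large / unresponsive stripes)."""
    base = ndimage.median_filter(profile, size=max(9, profile.size // 10 * 2 + 1))
    resid = profile - base
    mad = np.median(np.abs(resid - np.median(resid)))
    noise = 1.4826 * mad if mad > 0 else resid.std()
    if noise == 0:
        return np.zeros(profile.size, dtype=bool)
    return np.abs(resid) > snr * noise


def sorting_stripe_filter(
    sinogram,
    params: Optional[StripeFilterParams] = None,
    return_report: bool = False,
):
    params = params or StripeFilterParams(method="sorting")
    sino = _as_sino(sinogram)

    order = np.argsort(sino, axis=0, kind="stable")
    srt = np.take_along_axis(sino, order, axis=0)
    med = ndimage.median_filter(srt, size=(1, params.window), mode="nearest")
    out = np.empty_like(sino)
    np.put_along_axis(out, order, med, axis=0)

    replaced: list[int] = []
    if params.snr is not None:
        profile = np.median(sino, axis=0)
        flag = _detect_stripes(profile, params.snr)
        if flag.any() and not flag.all():
            cols = np.arange(sino.shape[1])
            good = cols[~flag]
            for r in range(out.shape[0]):
                out[r, flag] = np.interp(cols[flag], good, out[r, good])
            replaced = cols[flag].tolist()
    if return_report:
        return out, {"replaced_columns": replaced}
    return out
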