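"""Flat/dark-field correction and beam-profile diagnostics.

Applied to raw frames before the helical-to-standard conversion: per pixel

    corrected = (I - dark) / (flat - dark)

which removes the fixed beam profile and multiplicative detector gain to the
extent the references capture them.  Pixels whose flat-dark difference falls
below a floor are masked and filled from the nearest valid pixel in the same
row (nearest-in-row keeps column statistics intact for ring analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError
from .geometry import ProjectionStack

__all__ = ["FlatDarkSet", "flat_dark_correct", "vertical_flux_drop"]


@dataclass
class FlatDarkSet:
    """One or more beam-only (flat) and zero-beam (dark) reference frames.

    Multiple frames are reduced by median (default; robust against
    transients) or mean.  ``bad_pixel_mask`` flags pixels where the reduced
    flat does not exceed the reduced dark; more than 1% such pixels raises.
    """

    flats: np.ndarray
    darks: np.ndarray
    reduction: str = "median"

    def __post_init__(self) -> None:
        self.flats = _as_stack(self.flats)
        self.darks = _as_stack(self.darks)
        if self.flats.shape[1:] != self.darks.shape[1:]:
            raise GeometryError("flat and dark frames must share one shape")
        if self.reduction not in ("median", "mean"):
            raise GeometryError(f"unknown reduction {self.reduction!r}")
        red = np.median if self.reduction == "median" else np.mean
        self.flat = red(self.flats.astype(np.float64), axis=0)
        self.dark = red(self.darks.astype(np.float64), axis=0)
        self.bad_pixel_mask = self.flat <= self.dark
        frac_bad = self.bad_pixel_mask.mean()
        if frac_bad > 0.01:
            raise GeometryError(
                f"{100 * frac_bad:.1f}% of pixels have flat <= dark; "
                "references look unusable"
            )


def _as_stack(frames) -> np.ndarray:
    a = np.asarray(frames)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3:
        raise GeometryError("reference frames must be 2D or a stack of 2D frames")
    return a


def _fill_nearest_in_row(frame: np.ndarray, bad: np.ndarray) -> None:
    """In-place: replace flagged pixels by the nearest valid pixel of the row."""
    for r in np.nonzero(bad.any(axis=1))[0]:
        row_bad = bad[r]
        good = np.nonzero(~row_bad)[0]
        if good.size == 0:
            continue  # whole row invalid; leave to the caller's mask
        idx = np.searchsorted(good, np.nonzero(row_bad)[0])
        idx = np.clip(idx, 0, good.size - 1)
        left = good[np.maximum(idx - 1, 0)]
        right = good[idx]
        cols = np.nonzero(row_bad)[0]
        nearest = np.where(np.abs(cols - left) <= np.abs(cols - right), left, right)
        frame[r, cols] = frame[r, nearest]


def flat_dark_correct(
    raw: ProjectionStack, ref: FlatDarkSet, eps_frac: float = 1e-6
) -> ProjectionStack:
    """Background-correct a raw stack: ``(I - dark) / (flat - dark)``.

    ``eps_frac`` sets the flat-minus-dark floor as a fraction of the flat
    dynamic range; pixels at or below it are masked and filled by the
    nearest valid pixel in their row.  Output role is ``corrected``.
    """
    if raw.frame_shape != ref.flat.shape:
        raise GeometryError(
            f"frame shape {raw.frame_shape} != reference shape {ref.flat.shape}"
        )
    denom = ref.flat - ref.dark
    eps = eps_frac * max(float(ref.flat.max() - ref.dark.min()), 1.0)
    bad = denom <= eps
    denom_safe = np.where(bad, 1.0, denom)
    frames = (raw.frames.astype(np.float64) - ref.dark) / denom_safe
    if bad.any():
        for k in range(frames.shape[0]):
            _fill_nearest_in_row(frames[k], bad)
    np.clip(frames, 0.0, None, out=frames)
    return ProjectionStack(
        frames=frames, role="corrected", geometry=raw.geometry, mask=raw.mask
    )


def vertical_flux_drop(
    flat_frame: np.ndarray, column_band: Optional[tuple] = None
) -> float:
    """Centre-to-edge drop of the vertical beam profile, in percent.

    The profile is the row-wise mean over ``column_band`` (``(first, last)``
    columns, default all).  The drop uses the worse (lower) of the two edge
    rows:  ``100 * (max - min(first_row, last_row)) / max``.
    """
    frame = np.asarray(flat_frame, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[0] < 3:
        raise GeometryError("flat frame must be 2D with at least 3 rows")
    if column_band is None:
        band = frame
    else:
        c0, c1 = column_band
        band = frame[:, c0:c1]
    profile = band.mean(axis=1)
    top = float(profile.max())
    if top <= 0:
        raise GeometryError("flat profile must be positive")
    edge = min(float(profile[0]), float(profile[-1]))
    return 100.0 * (top - edge) / top
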