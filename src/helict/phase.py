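"""Single-distance TIE (Paganin-type) phase retrieval.

For a homogeneous weak-phase object with fixed refractive ratio
``delta/beta``, the edge-enhanced intensity ``I`` measured after free-space
propagation over ``SDD`` is deconvolved by the low-pass filter

    T = -ln( IFFT[ FFT[I] / (1 + pi * lambda * SDD * (delta/beta) * |q|^2) ] )

with ``|q|`` the spatial frequency in cycles/m on the detector grid.  The
filter has unit gain at zero frequency, so a uniform frame ``c`` maps to
``-ln c``, and ``delta/beta -> 0`` collapses it to plain ``-ln`` (pure
absorption).  The output is the attenuation line integral ``mu * thickness``
(equivalently ``(4 pi / lambda) *`` beta path integral), monotone in object
thickness.

Frames are edge-padded to twice their size before the FFT to suppress
wrap-around; the beam is parallel, so magnification is 1 and the effective
pixel is the binned detector pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .errors import DataError, GeometryError
from .geometry import ProjectionStack, ScanGeometry
from .simulate import wavelength_m

__all__ = ["RetrievalParams", "tie_filter", "tie_filter_stack"]


@dataclass
class RetrievalParams:
    """Parameters of the single-distance retrieval filter.

    delta_beta : ratio delta/beta of the assumed homogeneous material
    energy_kev : photon energy (keV)
    sdd_m      : propagation (sample-detector) distance (m)
    pixel_mm   : effective detector pixel (binning-aware), mm
    epsilon    : additive regularization floor on the denominator
    max_nonpositive_frac : tolerated fraction of nonpositive input pixels;
        those are masked to the smallest positive frame value before the log
    """

    delta_beta: float = 2000.0
    energy_kev: float = 30.0
    sdd_m: float = 1.5
    pixel_mm: float = 0.013
    epsilon: float = 0.0
    max_nonpositive_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.delta_beta < 0 or self.epsilon < 0:
            raise GeometryError("delta_beta and epsilon must be non-negative")
        if self.pixel_mm <= 0 or self.sdd_m < 0:
            raise GeometryError("pixel_mm must be positive and sdd_m >= 0")

    @classmethod
    def from_geometry(cls, geometry: ScanGeometry, delta_beta: float = 2000.0):
        return cls(
            delta_beta=delta_beta,
            energy_kev=geometry.energy_kev,
            sdd_m=geometry.sdd_m,
            pixel_mm=geometry.pixel_eff_mm,
        )


def tie_filter(frame: np.ndarray, params: RetrievalParams) -> np.ndarray:
    """Retrieve the attenuation (thickness-proportional) map of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise GeometryError("tie_filter expects a single 2D frame")
    nonpos = frame <= 0
    if nonpos.any():
        frac = nonpos.mean()
        if frac > params.max_nonpositive_frac:
            raise DataError(
                f"{100 * frac:.2f}% nonpositive pixels exceed the mask budget "
                f"({100 * params.max_nonpositive_frac:.2f}%)"
            )
        floor = frame[~nonpos].min()
        frame = np.where(nonpos, floor, frame)

    ny, nx = frame.shape
    py = sp_fft.next_fast_len(2 * ny)
    px = sp_fft.next_fast_len(2 * nx)
    padded = np.pad(frame, ((0, py - ny), (0, px - nx)), mode="edge")

    lam = wavelength_m(params.energy_kev)
    d_m = params.pixel_mm * 1e-3
    qy = sp_fft.fftfreq(py, d=d_m)
    qx = sp_fft.fftfreq(px, d=d_m)
    q2 = qy[:, None] ** 2 + qx[None, :] ** 2
    denom = 1.0 + np.pi * lam * params.sdd_m * params.delta_beta * q2 + params.epsilon

    filt = sp_fft.ifft2(sp_fft.fft2(padded) / denom).real[:ny, :nx]
    return -np.log(np.clip(filt, 1e-12, None))


def tie_filter_stack(stack: ProjectionStack, params=None) -> ProjectionStack:
    """Apply :func:`tie_filter` to every frame of a stack.

    Default parameters come from the stack's geometry with delta/beta = 2000.
    Gap rows (invalid in the stack mask) are carried through as NaN.
    """
    if params is None:
        params = RetrievalParams.from_geometry(stack.geometry)
    out = np.empty(stack.frames.shape, dtype=np.float64)
    for k in range(stack.n_frames):
        frame = np.asarray(stack.frames[k], dtype=np.float64)
        if stack.mask is not None and not stack.mask[k].all():
            valid = stack.mask[k]
            work = frame.copy()
            fill = np.nanmedian(frame[valid]) if valid.any() else 1.0
            work[~valid] = fill
            res = tie_filter(work, params)
            res[~valid] = np.nan
            out[k] = res
        else:
            out[k] = tie_filter(frame, params)
    return ProjectionStack(
        frames=out,
        role="phase-retrieved",
        geometry=stack.geometry,
        mask=stack.mask,
        angle_offset=stack.angle_offset,
    )
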