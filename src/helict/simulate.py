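"""Synthetic phantoms and a forward model for helical/standard PBI scans.

The simulator provides the ground-truth test bed for every downstream stage:

* voxelized phantoms carrying the complex refractive index decrement pair
  (delta, beta) per voxel — a 3D-printed hydrogel grid scaffold in a water
  cylinder, and a bar-pattern resolution phantom;
* an ideal parallel-beam projector (line integrals of delta and beta);
* a weak-defocus transport-of-intensity (TIE) forward model that converts the
  two path-integral maps into an edge-enhanced intensity frame — the exact
  forward counterpart of the single-distance phase-retrieval filter, which is
  what makes the retrieval stage testable by inversion;
* a detector model with the classic ring-artifact sources: fixed-pattern
  per-pixel gain errors, stuck (dead) pixels, a non-uniform vertical beam
  profile, and Poisson counting noise.

Propagation is the linearized TIE operator, not full Fresnel diffraction;
see docs/methods.md for what that does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ResolutionError
from .geometry import ProjectionStack, ScanGeometry

__all__ = [
    "PhantomVolume",
    "DetectorModel",
    "SimulatedScan",
    "WATER_DELTA_30KEV",
    "WATER_BETA_30KEV",
    "wavelength_m",
    "make_scaffold_phantom",
    "make_bar_phantom",
    "make_blob_phantom",
    "project_parallel",
    "apply_pbi_contrast",
    "simulate_scan",
]

#: hc in m*keV: lambda[m] = 1.23984193e-9 / E[keV]
_HC_M_KEV = 1.23984193e-9

#: water refractive-index decrement / absorption index at 30 keV (approximate)
WATER_DELTA_30KEV = 2.56e-7
WATER_BETA_30KEV = 1.28e-10

LABELS = {"air": 0, "water": 1, "strand": 2, "bar": 3}


def wavelength_m(energy_kev: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV."""
    if energy_kev <= 0:
        raise GeometryError("photon energy must be positive")
    return _HC_M_KEV / energy_kev


@dataclass
class PhantomVolume:
    """Voxelized (delta, beta) phantom, axes ``[z, y, x]`` (row, in-plane).

    The in-plane grid must be square and the object should stay inside the
    inscribed circle so that projections at all angles see the full object.
    """

    delta: np.ndarray
    beta: np.ndarray
    voxel_mm: float
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.delta.shape != self.beta.shape or self.delta.ndim != 3:
            raise GeometryError("delta and beta must be 3D arrays of equal shape")
        if self.delta.shape[1] != self.delta.shape[2]:
            raise GeometryError("in-plane phantom grid must be square")
        if self.voxel_mm <= 0:
            raise GeometryError("voxel size must be positive")
        if np.any(self.delta < 0) or np.any(self.beta < 0):
            raise GeometryError("delta and beta must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.delta.shape

    @property
    def n_rows(self) -> int:
        return self.delta.shape[0]


@dataclass
class DetectorModel:
    """Fixed-pattern detector defects, beam profile and counting statistics.

    With ``gain_map=None``, ``dead_pixels=None``, ``flux_profile=None`` and
    ``counts=None`` the simulation is deterministic and defect-free and the
    frames stay floating point (ideal transmission).  With ``counts`` set,
    frames are Poisson-sampled at that mean full-flux count and quantized to
    16-bit unsigned integers.

    ``dead_pixels`` is a sequence of ``(row, col)`` pairs stuck at
    ``dead_value`` (count units when ``counts`` is set).
    """

    gain_map: Optional[np.ndarray] = None
    dead_pixels: Optional[Sequence[tuple]] = None
    dead_value: float = 0.0
    flux_profile: Optional[np.ndarray] = None
    counts: Optional[float] = None
    dark_level: float = 0.0
    seed: int = 0

    @classmethod
    def with_defects(
        cls,
        n_rows: int,
        n_cols: int,
        gain_std: float = 0.015,
        n_dead: int = 3,
        flux_drop: float = 0.0,
        counts: Optional[float] = 2.0e4,
        dead_value: float = 1.0e3,
        seed: int = 0,
    ) -> "DetectorModel":
        """A detector with the package's default ring-artifact sources:
        multiplicative fixed-pattern gain (std ``gain_std``), ``n_dead`` stuck
        pixels, and an optional Gaussian vertical flux profile whose
        centre-to-edge drop is ``flux_drop`` (fraction of the peak)."""
        rng = np.random.default_rng(seed)
        gain = 1.0 + gain_std * rng.standard_normal((n_rows, n_cols))
        gain = np.clip(gain, 0.5, 1.5)
        dead = [
            (int(r), int(c))
            for r, c in zip(
                rng.integers(0, n_rows, n_dead), rng.integers(0, n_cols, n_dead)
            )
        ]
        flux = None
        if flux_drop > 0:
            if not flux_drop < 1:
                raise GeometryError("flux_drop must be in [0, 1)")
            rows = np.arange(n_rows) - (n_rows - 1) / 2
            half = (n_rows - 1) / 2 if n_rows > 1 else 1.0
            sigma = half / math.sqrt(2.0 * math.log(1.0 / (1.0 - flux_drop)))
            flux = np.exp(-0.5 * (rows / sigma) ** 2)
        return cls(
            gain_map=gain,
            dead_pixels=dead,
            dead_value=dead_value,
            flux_profile=flux,
            counts=counts,
            seed=seed,
        )

    def realize(self, n_rows: int, n_cols: int):
        """Gain map and flux profile as concrete arrays of the given shape."""
        if self.gain_map is None:
            gain = np.ones((n_rows, n_cols))
        else:
            gain = np.asarray(self.gain_map, dtype=np.float64)
            if gain.shape != (n_rows, n_cols):
                raise GeometryError(
                    f"gain map shape {gain.shape} != detector ({n_rows}, {n_cols})"
                )
            if np.any(gain <= 0):
                raise GeometryError("gain factors must be positive")
        if self.flux_profile is None:
            flux = np.ones(n_rows)
        else:
            flux = np.asarray(self.flux_profile, dtype=np.float64)
            if flux.shape != (n_rows,):
                raise GeometryError("flux profile must have one value per row")
            if np.any(flux <= 0):
                raise GeometryError("flux profile must be positive")
        return gain, flux


# ---------------------------------------------------------------------- #
# phantoms
# ---------------------------------------------------------------------- #
def _default_materials(energy_kev: float = 30.0, strand_contrast: float = 1.8) -> dict:
    """(delta, beta) per material.  The strand absorbs ``strand_contrast``
    times more than water so a 0.5 mm strand gives ~1-2% flat-corrected
    transmission contrast (the low-density hydrogel regime); its delta/beta
    ratio is pinned to 2000 to match the retrieval default."""
    scale = (30.0 / energy_kev) ** 2  # delta ~ 1/E^2
    beta_w = WATER_BETA_30KEV * (30.0 / energy_kev) ** 3  # mu ~ 1/E^3 (approx.)
    delta_w = WATER_DELTA_30KEV * scale
    beta_s = strand_contrast * beta_w
    return {
        "air": (0.0, 0.0),
        "water": (delta_w, beta_w),
        "strand": (2000.0 * beta_s, beta_s),
        "bar": (2000.0 * 4.0 * beta_w, 4.0 * beta_w),
    }


def _cylinder_mask(n_xy: int, radius_vox: float) -> np.ndarray:
    c = (n_xy - 1) / 2
    yy, xx = np.mgrid[0:n_xy, 0:n_xy]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def make_scaffold_phantom(
    strand_diameter_mm: float = 0.5,
    spacing_mm: float = 1.0,
    block_mm: tuple = (10.0, 10.0, 5.0),
    voxel_mm: float = 0.013,
    height_mm: Optional[float] = None,
    container_radius_mm: Optional[float] = None,
    n_xy: Optional[int] = None,
    energy_kev: float = 30.0,
    materials: Optional[dict] = None,
    edge_smooth_vox: float = 0.0,
) -> PhantomVolume:
    """Grid scaffold of cylindrical strands inside a water cylinder.

    Alternating layers of parallel strands run along x and y on a square grid
    (``floor(width / spacing) + 1`` strands per layer), layer thickness equal
    to the strand diameter, mimicking an extrusion-printed hydrogel lattice.
    ``strand_diameter_mm = 0`` produces a plain water cylinder.

    ``edge_smooth_vox`` Gaussian-smooths the (delta, beta) maps by that many
    voxels: material interfaces in soft matter are not voxel-sharp, and a
    band-limited phantom keeps reconstruction ringing out of artifact
    metrics.  Labels stay binary.

    The voxel size must resolve the strand: ``voxel_mm <= diameter / 5``.
    """
    if strand_diameter_mm > 0 and voxel_mm > strand_diameter_mm / 5:
        raise ResolutionError(
            f"voxel {voxel_mm} mm too coarse for {strand_diameter_mm} mm strands "
            "(need <= diameter / 5)"
        )
    bx, by, bz = block_mm
    mats = _default_materials(energy_kev) if materials is None else materials
    if container_radius_mm is None:
        container_radius_mm = 0.62 * math.hypot(bx, by)
    if n_xy is None:
        n_xy = int(math.ceil(2.15 * container_radius_mm / voxel_mm))
    if height_mm is None:
        height_mm = bz
    n_z = int(round(height_mm / voxel_mm))

    labels = np.zeros((n_z, n_xy, n_xy), dtype=np.uint8)
    water = _cylinder_mask(n_xy, container_radius_mm / voxel_mm)
    labels[:, water] = LABELS["water"]

    if strand_diameter_mm > 0:
        r_vox = strand_diameter_mm / 2 / voxel_mm
        c = (n_xy - 1) / 2
        cz = (n_z - 1) / 2
        n_strand = int(math.floor(bx / spacing_mm)) + 1
        # strand axis positions across the block, centred
        offs = (np.arange(n_strand) - (n_strand - 1) / 2) * (spacing_mm / voxel_mm)
        n_layers = max(1, int(round(bz / strand_diameter_mm)))
        layer_h = strand_diameter_mm / voxel_mm
        half_len = bx / 2 / voxel_mm
        zz = np.arange(n_z)[:, None, None]
        yy = np.arange(n_xy)[None, :, None]
        xx = np.arange(n_xy)[None, None, :]
        for layer in range(n_layers):
            z0 = cz + (layer - (n_layers - 1) / 2) * layer_h
            along_x = layer % 2 == 0
            for o in offs:
                if along_x:  # strand axis parallel to x, offset in y
                    d2 = (zz - z0) ** 2 + (yy - (c + o)) ** 2
                    inside = (d2 <= r_vox**2) & (np.abs(xx - c) <= half_len)
                else:
                    d2 = (zz - z0) ** 2 + (xx - (c + o)) ** 2
                    inside = (d2 <= r_vox**2) & (np.abs(yy - c) <= half_len)
                labels[np.broadcast_to(inside, labels.shape)] = LABELS["strand"]
        # strands exist only inside the water container
        labels[:, ~water] = LABELS["air"]

    delta = np.zeros_like(labels, dtype=np.float64)
    beta = np.zeros_like(delta)
    for name, lab in LABELS.items():
        if name in mats:
            d, b = mats[name]
            sel = labels == lab
            delta[sel] = d
            beta[sel] = b
    if edge_smooth_vox > 0:
        delta = ndimage.gaussian_filter(delta, edge_smooth_vox)
        beta = ndimage.gaussian_filter(beta, edge_smooth_vox)
    return PhantomVolume(
        delta,
        beta,
        voxel_mm,
        labels=labels,
        meta={
            "kind": "scaffold",
            "strand_diameter_mm": strand_diameter_mm,
            "spacing_mm": spacing_mm,
            "block_mm": tuple(block_mm),
            "n_strands_per_layer": 0
            if strand_diameter_mm == 0
            else int(math.floor(bx / spacing_mm)) + 1,
            "materials": mats,
        },
    )


@dataclass
class BarGroup:
    """One spatial-frequency group of a bar-pattern phantom."""

    freq_lp_mm: float
    y_slice: slice
    resolvable: bool


def make_bar_phantom(
    frequencies_lp_mm: Sequence[float],
    size_mm: tuple = (5.0, 5.0),
    depth_mm: float = 2.0,
    voxel_mm: float = 0.013,
    energy_kev: float = 30.0,
) -> tuple[PhantomVolume, list[BarGroup]]:
    """Bar-pattern resolution phantom: groups of parallel bars with 50% duty
    cycle, one frequency per group, stacked along y; bars modulate along x
    and run the full depth along z.  A group whose half-period is sampled by
    fewer than 2 voxels is flagged unresolvable (and left empty)."""
    wx, wy = size_mm
    n_x = int(round(wx / voxel_mm))
    n_y = int(round(wy / voxel_mm))
    n_xy = int(math.ceil(1.6 * max(n_x, n_y)))
    n_z = max(4, int(round(depth_mm / voxel_mm)))
    mats = _default_materials(energy_kev)

    labels = np.zeros((n_z, n_xy, n_xy), dtype=np.uint8)
    c = (n_xy - 1) / 2
    labels[:, _cylinder_mask(n_xy, 0.45 * n_xy)] = LABELS["water"]

    groups: list[BarGroup] = []
    band = n_y // max(1, len(frequencies_lp_mm))
    y0 = int(c - n_y / 2)
    x = np.arange(n_xy) - c
    for gi, f in enumerate(frequencies_lp_mm):
        half_period_vox = 1.0 / (2.0 * f) / voxel_mm
        ys = slice(y0 + gi * band, y0 + (gi + 1) * band)
        ok = half_period_vox >= 2.0
        if ok:
            phase = np.floor((x + n_x / 2) / half_period_vox).astype(int)
            bar_cols = (phase % 2 == 0) & (np.abs(x) <= n_x / 2)
            labels[:, ys, bar_cols] = LABELS["bar"]
        groups.append(BarGroup(freq_lp_mm=f, y_slice=ys, resolvable=ok))

    delta = np.zeros_like(labels, dtype=np.float64)
    beta = np.zeros_like(delta)
    for name, lab in LABELS.items():
        d, b = mats[name]
        sel = labels == lab
        delta[sel] = d
        beta[sel] = b
    vol = PhantomVolume(
        delta, beta, voxel_mm, labels=labels, meta={"kind": "bars", "materials": mats}
    )
    return vol, groups


def make_blob_phantom(
    n_rows: int,
    n_xy: int,
    voxel_mm: float,
    delta_beta: float = 2000.0,
    beta_peak: float = 4.0 * WATER_BETA_30KEV,
    sigma_vox: float = 6.0,
) -> PhantomVolume:
    """Smooth homogeneous Gaussian blob (delta/beta fixed) — the weak-phase
    object used to exercise the TIE forward/inverse pair."""
    z = np.arange(n_rows) - (n_rows - 1) / 2
    y = np.arange(n_xy) - (n_xy - 1) / 2
    r2 = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + y[None, None, :] ** 2
    )
    beta = beta_peak * np.exp(-0.5 * r2 / sigma_vox**2)
    return PhantomVolume(
        delta_beta * beta, beta, voxel_mm, meta={"kind": "blob", "sigma_vox": sigma_vox}
    )


# ---------------------------------------------------------------------- #
# forward model
# ---------------------------------------------------------------------- #
def project_parallel(
    volume: PhantomVolume,
    angle: float,
    row_window: Optional[tuple] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-beam line integrals of delta and beta at one rotation angle.

    Returns ``(delta_integral, beta_integral)`` frames in mm units (value x
    path length), shape ``(n_rows, n_xy)``.  The detector column axis is
    ``u = (cos a, sin a)`` in the (x, y) plane and rays run along
    ``(-sin a, cos a)``; rotation centre is the in-plane grid centre
    ``(n-1)/2``, so projections at ``a`` and ``a + pi`` are exact horizontal
    mirror images of each other (the parallel-beam conjugacy the conversion
    flip relies on).  Sampling is bilinear.
    """
    nz, n, _ = volume.shape
    if row_window is None:
        first, nrows = 0, nz
    else:
        first, nrows = row_window
        if first < 0 or first + nrows > nz:
            raise GeometryError(
                f"row window [{first}, {first + nrows}) outside volume of {nz} rows"
            )
    c = (n - 1) / 2.0
    j = np.arange(n) - c  # detector column coordinate
    s = np.arange(n) - c  # ray parameter
    cos_a, sin_a = math.cos(angle), math.sin(angle)
    xx = c + j[None, :] * cos_a - s[:, None] * sin_a
    yy = c + j[None, :] * sin_a + s[:, None] * cos_a
    shape = (nrows, n, n)  # (detector row, ray parameter, detector column)
    coords = np.empty((3,) + shape)
    coords[0] = np.arange(first, first + nrows)[:, None, None]
    coords[1] = yy[None, :, :]
    coords[2] = xx[None, :, :]

    d_int = ndimage.map_coordinates(
        volume.delta, coords, order=1, mode="grid-constant"
    ).sum(axis=1)
    b_int = ndimage.map_coordinates(
        volume.beta, coords, order=1, mode="grid-constant"
    ).sum(axis=1)
    d_int *= volume.voxel_mm
    b_int *= volume.voxel_mm
    return d_int, b_int


def apply_pbi_contrast(
    delta_int_mm: np.ndarray,
    beta_int_mm: np.ndarray,
    energy_kev: float,
    sdd_m: float,
    pixel_mm: float,
    clip_floor: float = 1e-9,
) -> np.ndarray:
    """Weak-defocus TIE forward model: path integrals -> intensity frame.

    With ``mu``-thickness ``A = (4 pi / lambda) * beta_int`` and phase
    ``phi = -(2 pi / lambda) * delta_int``, free-space propagation over the
    sample-detector distance ``z`` gives, to first order,

        I = exp(-A) * (1 - (lambda z / 2 pi) * lap(phi))
          = exp(-A) * (1 + z * lap(delta_int))

    (Laplacian in 1/m^2, integrals converted to metres).  ``sdd_m = 0`` is
    the contact regime: pure absorption contrast, no fringes.  The output is
    the transmission relative to the incident beam, floored at ``clip_floor``
    to keep strongly-fringed edges physical.
    """
    if delta_int_mm.shape != beta_int_mm.shape:
        raise GeometryError("delta and beta integral frames must have equal shapes")
    lam = wavelength_m(energy_kev)
    a = (4.0 * np.pi / lam) * (beta_int_mm * 1e-3)
    i_abs = np.exp(-a)
    if sdd_m == 0:
        return i_abs
    px_m = pixel_mm * 1e-3
    lap = ndimage.laplace(delta_int_mm * 1e-3, mode="nearest") / px_m**2
    out = i_abs * (1.0 + sdd_m * lap)
    return np.clip(out, clip_floor, None)


@dataclass
class SimulatedScan:
    """Raw frames plus the flat/dark reference frames of one simulated scan."""

    projections: ProjectionStack
    flats: np.ndarray
    darks: np.ndarray
    detector: DetectorModel


def _frame_windows(geometry: ScanGeometry):
    """(floor shift, fractional part) of the vertical offset per projection."""
    if geometry.mode == "helical":
        v = geometry.rows_per_projection
        kv = np.arange(geometry.n_frames) * v
        s = np.floor(kv + 1e-9).astype(int)
        frac = kv - s
        frac[frac < 1e-9] = 0.0
        return s, frac
    n = geometry.n_frames
    return np.zeros(n, dtype=int), np.zeros(n)


def simulate_scan(
    volume: PhantomVolume,
    geometry: ScanGeometry,
    detector: Optional[DetectorModel] = None,
    n_flats: int = 4,
    n_darks: int = 4,
) -> SimulatedScan:
    """Simulate one helical or standard PBI scan of ``volume``.

    The edge-enhanced transmission is computed once per distinct rotation
    angle on the full phantom height, then windowed to the detector rows of
    each projection (fractional window offsets are linearly interpolated in
    z, mirroring the conversion's row interpolation).  Detector effects are
    applied per frame:

        counts = Poisson( mean_counts * T * flux[row] * gain[row, col] )

    with stuck pixels overwritten last and frames quantized to 16-bit when
    ``detector.counts`` is set.  Flats are beam-only frames sharing the same
    gain/dead-pixel defects and noise; darks are zero-beam offset frames.
    Everything is reproducible from ``detector.seed``.
    """
    detector = detector or DetectorModel()
    m, n = geometry.n_rows, geometry.n_cols
    if volume.shape[1] != n:
        raise GeometryError(
            f"phantom in-plane size {volume.shape[1]} != detector columns {n}"
        )
    shifts, fracs = _frame_windows(geometry)
    need = int(shifts.max() + (fracs.max() > 0)) + m
    if geometry.mode == "helical" and volume.n_rows < need:
        raise GeometryError(
            f"helical travel needs {need} phantom rows, volume has {volume.n_rows}"
        )
    if geometry.mode == "standard" and volume.n_rows < m:
        raise GeometryError("phantom shorter than the detector")

    gain, flux = detector.realize(m, n)
    angles = geometry.angles()
    # distinct angle <-> k mod n_proj (helical revisits angles every turn)
    angle_index = np.arange(geometry.n_frames) % geometry.n_proj

    ss = np.random.SeedSequence(detector.seed)
    rng_proj, rng_flat, rng_dark = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    float_out = detector.counts is None
    dtype = np.float64 if float_out else np.uint16
    frames = np.empty((geometry.n_frames, m, n), dtype=dtype)

    cache: dict[int, np.ndarray] = {}
    for k in range(geometry.n_frames):
        ai = int(angle_index[k])
        if ai not in cache:
            d_int, b_int = project_parallel(volume, float(angles[k]))
            cache[ai] = apply_pbi_contrast(
                d_int,
                b_int,
                geometry.energy_kev,
                geometry.sdd_m,
                geometry.pixel_eff_mm,
            )
        t_full = cache[ai]
        s, f = int(shifts[k]), float(fracs[k])
        if f == 0.0:
            t = t_full[s : s + m]
        else:
            t = (1.0 - f) * t_full[s : s + m] + f * t_full[s + 1 : s + m + 1]
        mean = t * flux[:, None] * gain
        frames[k] = _detect(mean, detector, rng_proj, float_out)

    flat_mean = np.broadcast_to(flux[:, None] * gain, (m, n))
    flats = np.stack(
        [_detect(flat_mean, detector, rng_flat, float_out) for _ in range(n_flats)]
    )
    dark_mean = np.zeros((m, n))
    darks = np.stack(
        [
            _detect(dark_mean, detector, rng_dark, float_out, dark=True)
            for _ in range(n_darks)
        ]
    )
    stack = ProjectionStack(frames=frames, role="raw", geometry=geometry)
    return SimulatedScan(projections=stack, flats=flats, darks=darks, detector=detector)


def _detect(mean, detector: DetectorModel, rng, float_out: bool, dark: bool = False):
    """One detector readout of the given mean relative intensity."""
    if float_out:
        out = np.array(mean, dtype=np.float64, copy=True)
        if detector.dead_pixels:
            for r, c in detector.dead_pixels:
                out[r, c] = detector.dead_value
        return out
    lam = mean * detector.counts + detector.dark_level
    if dark:
        lam = np.full(mean.shape, detector.dark_level)
    out = rng.poisson(lam).astype(np.float64)
    if detector.dead_pixels and not dark:
        for r, c in detector.dead_pixels:
            out[r, c] = detector.dead_value
    return np.clip(out, 0, 65535).astype(np.uint16)
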