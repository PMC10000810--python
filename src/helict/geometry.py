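"""Acquisition geometry for helical and standard parallel-beam PBI-CT scans.

A *standard* scan rotates the sample through exactly 180 degrees and records
``n_proj / 2`` projections on a fixed detector.  A *helical* scan rotates
continuously through ``n_rot`` full revolutions (360 degrees each, ``n_proj``
projections per revolution) while the rotation stage translates vertically at
constant speed.  The dimensionless helical pitch is

    p = s_v * t / h_FOV

where ``s_v`` is the vertical stage speed (mm/s), ``t`` the time per
revolution (s) and ``h_FOV = M * d`` the height of the active detector (mm).
Equivalently the stage advances ``v = p * M / n_proj`` detector rows per
projection, so projection ``k`` is vertically displaced by ``k * v`` rows.

Index conventions used throughout the package (0-based everywhere):

* projection ``k`` of a helical scan is at angle ``2*pi*k / n_proj``;
  projection ``k`` of a standard (or virtual) scan is at ``2*pi*k / n_proj``
  as well, with only ``n_proj / 2`` projections recorded (a half turn);
* global (virtual) row 0 coincides with detector row 0 of projection 0, and
  the continuous global row of local row ``i`` in projection ``k`` is
  ``g = i + k * v``;
* ``direction == "down"`` is the reference sense (stage moving downwards);
  ``"up"`` inverts the sign of the row displacement and is handled by
  reversing detector row order before/after conversion.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .errors import GeometryError, ModeError

__all__ = [
    "ScanGeometry",
    "ProjectionStack",
    "CoverageReport",
    "pitch",
    "rows_per_projection",
    "n_virtual_rows",
    "frame_row_support",
    "coverage_report",
]

#: relative tolerance for the two-of-three (pitch, stage travel, FOV) check
_CONSISTENCY_RTOL = 1e-9

#: frame roles a stack may carry
ROLES = ("raw", "corrected", "phase-retrieved", "virtual")


def pitch(s_v: float, t: float, h_fov: float) -> float:
    """Dimensionless helical pitch ``p = s_v * t / h_fov``.

    Parameters
    ----------
    s_v : float
        Vertical stage speed in mm/s.
    t : float
        Time for one full revolution in s.
    h_fov : float
        Height of the field of view (active detector height) in mm.
    """
    if s_v <= 0 or t <= 0 or h_fov <= 0:
        raise GeometryError(
            f"pitch requires positive arguments, got s_v={s_v}, t={t}, h_fov={h_fov}"
        )
    return s_v * t / h_fov


@dataclass
class ScanGeometry:
    """Acquisition parameters of one scan plus derived quantities.

    Any two of (``pitch``, ``stage_speed * rot_period``, FOV height) determine
    the third; supplying all three is allowed but must be consistent to
    1e-9 relative.

    Parameters
    ----------
    mode : {"helical", "standard"}
    pixel_mm : float
        Detector pixel size ``d`` in mm (before binning).
    n_rows : int
        Active detector rows ``M``.
    n_cols : int
        Detector columns ``N``.
    n_proj : int
        Projections per full revolution ``N_p`` (even).  A standard scan
        records ``n_proj / 2`` projections over 180 degrees.
    n_rot : int
        Number of revolutions ``N_R`` (helical only).
    pitch : float, optional
        Dimensionless helical pitch ``p``.
    stage_speed : float, optional
        Vertical stage speed ``s_v`` in mm/s.
    rot_period : float, optional
        Seconds per revolution ``t``.
    sdd_m : float
        Sample-to-detector distance in m.
    energy_kev : float
        Photon energy in keV.
    binning : int
        On-detector binning factor; effective pixel is ``pixel_mm * binning``.
    direction : {"down", "up"}
        Stage motion sense.
    exposure_s : float, optional
        Exposure time per projection in s.
    """

    mode: str
    pixel_mm: float
    n_rows: int
    n_cols: int
    n_proj: int
    n_rot: int = 1
    pitch: Optional[float] = None
    stage_speed: Optional[float] = None
    rot_period: Optional[float] = None
    sdd_m: float = 1.5
    energy_kev: float = 30.0
    binning: int = 1
    direction: str = "down"
    exposure_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("helical", "standard"):
            raise GeometryError(f"unknown scan mode {self.mode!r}")
        if self.direction not in ("down", "up"):
            raise GeometryError(f"unknown stage direction {self.direction!r}")
        if self.pixel_mm <= 0 or self.sdd_m < 0 or self.energy_kev <= 0:
            raise GeometryError("pixel_mm and energy_kev must be positive, sdd_m >= 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("detector must have at least one row and column")
        if self.n_proj < 2 or self.n_proj % 2:
            # an integer half-turn count is required by the k -> k' modulo rule
            raise GeometryError(f"n_proj must be even and >= 2, got {self.n_proj}")
        if self.n_rot < 1:
            raise GeometryError("n_rot must be >= 1")
        if int(self.binning) != self.binning or self.binning < 1:
            raise GeometryError("binning must be a positive integer")
        self._resolve_pitch()

    def _resolve_pitch(self) -> None:
        """Fill in pitch / stage_speed / rot_period from the others."""
        travel = None
        if self.stage_speed is not None and self.rot_period is not None:
            if self.stage_speed <= 0 or self.rot_period <= 0:
                raise GeometryError("stage_speed and rot_period must be positive")
            travel = self.stage_speed * self.rot_period
        if self.pitch is not None:
            if self.pitch <= 0:
                raise GeometryError(f"pitch must be positive, got {self.pitch}")
            if travel is not None:
                implied = travel / self.fov_height_mm
                if not math.isclose(implied, self.pitch, rel_tol=_CONSISTENCY_RTOL):
                    raise GeometryError(
                        f"inconsistent geometry: pitch={self.pitch} but "
                        f"s_v*t/h_FOV={implied}"
                    )
            elif self.stage_speed is not None:
                self.rot_period = self.pitch * self.fov_height_mm / self.stage_speed
            elif self.rot_period is not None:
                self.stage_speed = self.pitch * self.fov_height_mm / self.rot_period
        elif travel is not None:
            self.pitch = travel / self.fov_height_mm
        elif self.mode == "helical":
            raise GeometryError(
                "helical geometry needs pitch or both stage_speed and rot_period"
            )

    # ------------------------------------------------------------------ #
    # derived quantities
    # ------------------------------------------------------------------ #
    @property
    def fov_height_mm(self) -> float:
        """Active detector height ``h_FOV = M * d`` in mm."""
        return self.n_rows * self.pixel_mm

    @property
    def fov_width_mm(self) -> float:
        return self.n_cols * self.pixel_mm

    @property
    def pixel_eff_mm(self) -> float:
        """Effective (binned) pixel size in mm."""
        return self.pixel_mm * self.binning

    @property
    def rows_per_projection(self) -> float:
        """Vertical motion ``v = p * M / N_p`` in detector rows per projection."""
        if self.mode != "helical":
            raise ModeError("rows_per_projection is defined for helical scans only")
        v = self.pitch * self.n_rows / self.n_proj
        if v <= 0:
            raise GeometryError("rows per projection must be positive")
        return v

    @property
    def n_frames(self) -> int:
        """Number of acquired projections."""
        if self.mode == "helical":
            return self.n_rot * self.n_proj
        return self.n_proj // 2

    @property
    def n_virtual_rows(self) -> int:
        """Rows ``M'`` of the virtual standard projections assembled from this
        helical scan: ``M' = M + ceil(v * (N_R*N_p - 1))`` (package convention;
        global row 0 is detector row 0 of projection 0)."""
        if self.mode != "helical":
            raise ModeError("n_virtual_rows is defined for helical scans only")
        v = self.rows_per_projection
        return self.n_rows + math.ceil(v * (self.n_frames - 1) - 1e-12)

    def angles(self) -> np.ndarray:
        """Rotation angle of every projection, radians, angle 0 at k = 0."""
        k = np.arange(self.n_frames)
        return 2.0 * np.pi * k / self.n_proj

    def as_standard(self, n_rows: Optional[int] = None) -> "ScanGeometry":
        """The standard-mode geometry whose projections this helical scan's
        virtual projections emulate (``n_rows`` defaults to ``n_virtual_rows``)."""
        if self.mode != "helical":
            raise ModeError("as_standard converts helical geometries only")
        return dataclasses.replace(
            self,
            mode="standard",
            n_rows=self.n_virtual_rows if n_rows is None else n_rows,
            n_rot=1,
            pitch=None,
            stage_speed=None,
            rot_period=None,
        )

    def replace(self, **kw) -> "ScanGeometry":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------ #
    # serialization (flat key-value YAML; lengths mm, energy keV, times s)
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ScanGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def rows_per_projection(geometry: ScanGeometry) -> float:
    """Vertical stage motion in detector rows per projection (helical only)."""
    return geometry.rows_per_projection


def n_virtual_rows(geometry: ScanGeometry) -> int:
    return geometry.n_virtual_rows


@dataclass
class ProjectionStack:
    """An ordered stack of projection frames plus its geometry.

    ``frames`` is indexed ``[k, i, j]`` (projection, row, column).  ``mask``
    is an optional per-frame-row validity flag of shape ``(n_frames, n_rows)``
    used to mark rows of virtual projections that no helical frame supplied
    (pitch > 2 gaps).  ``angle_offset`` shifts all nominal angles by a
    constant (used by odd/even projection splitting).
    """

    frames: np.ndarray
    role: str
    geometry: ScanGeometry
    mask: Optional[np.ndarray] = None
    angle_offset: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise GeometryError("frames must be a 3D [projection, row, column] array")
        if self.role not in ROLES:
            raise GeometryError(f"unknown stack role {self.role!r}; expected {ROLES}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[:2]:
                raise GeometryError("mask must have shape (n_frames, n_rows)")
            bad = ~np.isfinite(self.frames) & self.mask[:, :, None]
            flat_ok = np.isfinite(self.frames) | ~self.mask[:, :, None]
        else:
            bad = ~np.isfinite(self.frames)
            flat_ok = None
        if np.any(bad):
            raise GeometryError("non-finite intensities outside the invalid-row mask")
        del flat_ok
        if self.role == "corrected" and np.nanmin(self.frames) < 0:
            raise GeometryError("corrected intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    def angles(self) -> np.ndarray:
        return self.geometry.angles()[: self.n_frames] + self.angle_offset

    def with_frames(self, frames: np.ndarray, role: Optional[str] = None) -> "ProjectionStack":
        return ProjectionStack(
            frames=frames,
            role=self.role if role is None else role,
            geometry=self.geometry,
            mask=self.mask,
            angle_offset=self.angle_offset,
        )


# ---------------------------------------------------------------------- #
# row coverage
# ---------------------------------------------------------------------- #
def frame_row_support(k: int, v: float, n_rows: int) -> tuple[int, int, float]:
    """Integer global rows served by helical frame ``k`` plus the weight.

    Returns ``(g_first, g_last, w)`` such that frame ``k`` can supply every
    integer virtual row ``g in [g_first, g_last]`` via

        value(g) = (1 - w) * frame[g - g_first] + w * frame[g - g_first + 1]

    where ``w = frac(-k*v) mod 1`` is the linear-interpolation weight on the
    upper source row (``w = 0`` whenever ``k*v`` is integral, in which case
    rows copy directly).  Contributions that would need row ``n_rows`` are
    excluded, so no extrapolation ever happens.
    """
    kv = k * v
    s = math.floor(kv + 1e-9)
    gf = kv - s
    if gf < 1e-9 or gf > 1 - 1e-9:
        # k*v integral (snap tolerance absorbs float jitter): direct copy
        s = round(kv)
        return s, s + n_rows - 1, 0.0
    # sample point for row g sits between local rows (g-s-1) and (g-s)
    return s + 1, s + n_rows - 1, 1.0 - gf


@dataclass
class CoverageReport:
    """Result of :func:`coverage_report`.

    ``hits[g]`` attributes every acquired detector pixel to the global row
    ``floor(i + k*v)`` so that ``hits.sum() == N_R * N_p * M`` exactly.
    ``sources[kp, g]`` counts the helical frames able to supply virtual row
    ``g`` of virtual projection ``kp`` (the quantity that matters for
    conversion); a *gap* is an interior row missing for at least one ``kp``.
    """

    n_virtual_rows: int
    hits: np.ndarray
    sources: np.ndarray
    gap_rows: np.ndarray
    interior: tuple[int, int]
    covers_sample: Optional[bool] = None

    @property
    def has_gaps(self) -> bool:
        return self.gap_rows.size > 0


def coverage_report(
    geometry: ScanGeometry, sample_height_mm: Optional[float] = None
) -> CoverageReport:
    """Per-row coverage of a helical scan.

    Interior gap rows exist iff pitch > 2 (up to edge effects at the scan
    start/end); the interior band excludes ``n_rows`` rows at either end.
    """
    if geometry.mode != "helical":
        raise ModeError("coverage_report requires a helical geometry")
    v = geometry.rows_per_projection
    m = geometry.n_rows
    n_half = geometry.n_proj // 2
    mp = geometry.n_virtual_rows

    hits = np.zeros(mp, dtype=np.int64)
    sources = np.zeros((n_half, mp), dtype=np.int32)
    for k in range(geometry.n_frames):
        s = math.floor(k * v + 1e-9)
        hits[s : s + m] += 1
        g0, g1, _w = frame_row_support(k, v, m)
        g1 = min(g1, mp - 1)
        if g0 <= g1:
            sources[k % n_half, g0 : g1 + 1] += 1

    lo, hi = m, mp - 1 - m  # interior band, clear of scan start/end effects
    missing_any = (sources == 0).any(axis=0)
    rows = np.arange(mp)
    gap_rows = rows[(rows >= lo) & (rows <= hi) & missing_any]

    covers = None
    if sample_height_mm is not None:
        covers = mp * geometry.pixel_mm >= sample_height_mm
    return CoverageReport(
        n_virtual_rows=mp,
        hits=hits,
        sources=sources,
        gap_rows=gap_rows,
        interior=(lo, hi),
        covers_sample=covers,
    )
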