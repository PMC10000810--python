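"""Helical-to-standard conversion: assemble virtual 180-degree projections.

This is the core algorithm of the package.  A helical scan records
``N_R * N_p`` frames of ``M`` rows while the stage translates by ``v`` rows
per projection.  Because a parallel-beam projection at angle ``a + pi`` is
the horizontal mirror of the one at ``a``, every helical frame can be folded
onto one of ``N_p / 2`` virtual standard projections:

* target projection:  ``k' = k mod (N_p / 2)``;
* horizontal flip iff the half-turn count ``floor(k / (N_p / 2))`` is odd;
* virtual row ``r`` of projection ``k'`` receives

      (1 - w) * I[i0, :] + w * I[i0 + 1, :],   i0 = floor(r - k*v),

  with ``w = frac(-k*v) mod 1`` the linear-interpolation weight on the upper
  source row (``w = 0`` whenever ``k*v`` is integral, in which case rows copy
  directly, and the edge row ``i0 = M - 1`` is then accepted as well — no
  source row is ever extrapolated).

For pitch < 2 several source frames supply the same ``(k', r)``; the
redundancy policy keeps exactly one contribution (default: the earliest
rotation, i.e. smallest ``k``; redundant rows are discarded).  For pitch > 2
some ``(k', r)`` have no source at all: those rows are flagged in the mask,
set to NaN, and reported — never silently interpolated.

The virtual stack has ``M' = M + ceil(v * (N_R*N_p - 1))`` rows and emulates
a standard scan of the full travel range; see the geometry module for the
index conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError
from .geometry import ProjectionStack, ScanGeometry, frame_row_support

__all__ = ["ConversionPlan", "plan_conversion", "convert"]

POLICIES = ("first", "average")


@dataclass
class ConversionPlan:
    """Per-source-frame routing table for the helical-to-standard conversion.

    Arrays are indexed by source projection ``k``:

    ``kprime``       target virtual projection ``k mod (N_p/2)``;
    ``flip``         column reversal flag (odd half-turn count);
    ``g_first``      first integer virtual row the frame serves;
    ``g_last``       last integer virtual row the frame serves;
    ``weight``       interpolation weight on the upper source row.
    """

    geometry: ScanGeometry
    v: float
    n_virtual_rows: int
    n_virtual_proj: int
    kprime: np.ndarray
    flip: np.ndarray
    g_first: np.ndarray
    g_last: np.ndarray
    weight: np.ndarray
    policy: str = "first"

    def table(self) -> list[dict]:
        """The full (k -> k', flip, shift, w) table, one dict per source."""
        return [
            {
                "k": int(k),
                "kprime": int(self.kprime[k]),
                "flip": bool(self.flip[k]),
                "g_first": int(self.g_first[k]),
                "g_last": int(self.g_last[k]),
                "w": float(self.weight[k]),
            }
            for k in range(self.kprime.size)
        ]


def plan_conversion(geometry: ScanGeometry, policy: str = "first") -> ConversionPlan:
    """Build the routing table for every source projection of a helical scan."""
    if geometry.mode != "helical":
        raise GeometryError("plan_conversion requires a helical geometry")
    if policy not in POLICIES:
        raise GeometryError(f"unknown redundancy policy {policy!r}; use {POLICIES}")
    v = geometry.rows_per_projection
    m = geometry.n_rows
    n_half = geometry.n_proj // 2
    n_src = geometry.n_frames

    k = np.arange(n_src)
    kprime = k % n_half
    flip = (k // n_half) % 2 == 1
    g_first = np.empty(n_src, dtype=int)
    g_last = np.empty(n_src, dtype=int)
    weight = np.empty(n_src)
    for kk in range(n_src):
        g_first[kk], g_last[kk], weight[kk] = frame_row_support(kk, v, m)
    return ConversionPlan(
        geometry=geometry,
        v=v,
        n_virtual_rows=geometry.n_virtual_rows,
        n_virtual_proj=n_half,
        kprime=kprime,
        flip=flip,
        g_first=g_first,
        g_last=g_last,
        weight=weight,
        policy=policy,
    )


def convert(
    stack: ProjectionStack,
    plan: Optional[ConversionPlan] = None,
    policy: Optional[str] = None,
) -> ProjectionStack:
    """Convert a corrected helical stack into virtual standard projections.

    Returns a stack of ``N_p / 2`` frames of ``M'`` rows with role
    ``virtual`` (input role is preserved in ``provenance``); its ``mask``
    marks rows every source frame missed (gaps, pitch > 2), which are NaN in
    the frames.  Conversion is linear in the input intensities and every
    virtual pixel traces to exactly one or two source pixels (the
    w-interpolation pair); per-projection source counts are recorded in the
    returned stack's ``provenance`` attribute.
    """
    if stack.role == "virtual":
        raise GeometryError("stack is already virtual")
    if stack.role == "raw":
        warnings.warn(
            "converting an uncorrected raw stack; flat/dark correction is "
            "normally applied first",
            stacklevel=2,
        )
    geometry = stack.geometry
    if plan is None:
        plan = plan_conversion(geometry, policy or "first")
    elif plan.geometry.to_dict() != geometry.to_dict():
        raise GeometryError("plan was built from a different geometry")
    pol = policy or plan.policy

    frames = stack.frames.astype(np.float64, copy=False)
    if geometry.direction == "up":
        # an upward-moving stage is a downward scan with rows reversed
        frames = frames[:, ::-1, :]
    n_half, mp = plan.n_virtual_proj, plan.n_virtual_rows
    m, n = geometry.n_rows, geometry.n_cols

    virt = np.zeros((n_half, mp, n))
    filled = np.zeros((n_half, mp), dtype=bool)
    counts = np.zeros((n_half, mp), dtype=np.int32)

    for k in range(frames.shape[0]):
        g0, g1 = int(plan.g_first[k]), min(int(plan.g_last[k]), mp - 1)
        if g1 < g0:
            continue
        w = float(plan.weight[k])
        src = frames[k, :, ::-1] if plan.flip[k] else frames[k]
        if w == 0.0:
            contrib = src[0 : g1 - g0 + 1]
        else:
            lo = src[0 : g1 - g0 + 1]
            hi = src[1 : g1 - g0 + 2]
            contrib = (1.0 - w) * lo + w * hi
        kp = int(plan.kprime[k])
        rows = slice(g0, g1 + 1)
        counts[kp, rows] += 1
        if pol == "first":
            sel = ~filled[kp, rows]
            virt[kp, rows][sel] = contrib[sel]  # basic slice -> in-place view
            filled[kp, rows] = True
        else:  # average
            virt[kp, rows] += contrib
            filled[kp, rows] = True

    if pol == "average":
        nz = counts > 0
        virt[nz] /= counts[nz][:, None]

    gaps = ~filled
    # rows at the scan start/end are never complete (the helix ramps onto and
    # off the object); true inter-rotation gaps are interior and mean p > 2
    interior = np.zeros(mp, dtype=bool)
    interior[m : mp - m] = True
    gap_rows = np.nonzero(gaps.any(axis=0) & interior)[0]
    edge_rows = np.nonzero(gaps.any(axis=0) & ~interior)[0]
    if gaps.any():
        virt[gaps] = np.nan
        if gap_rows.size:
            warnings.warn(
                f"{gap_rows.size} interior virtual rows have no source frame "
                "(pitch > 2 leaves inter-rotation gaps); they are NaN and "
                "flagged in the mask",
                stacklevel=2,
            )

    vgeom = geometry.as_standard(n_rows=mp)
    out = ProjectionStack(
        frames=virt, role="virtual", geometry=vgeom, mask=filled
    )
    out.provenance = {
        "source_role": stack.role,
        "policy": pol,
        "v_rows_per_projection": plan.v,
        "n_virtual_rows": mp,
        "source_counts_per_projection": counts.sum(axis=1).tolist(),
        "gap_rows": gap_rows.tolist(),
        "edge_rows": edge_rows.tolist(),
    }
    return out
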