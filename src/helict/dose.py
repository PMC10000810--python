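"""Pitch-aware surface-entry dose accounting.

The surface entry dose of a scan is approximated by

    D = rate * dt * N_eff

with ``rate`` the measured surface-entry dose rate (Gy/s), ``dt`` the
exposure per projection (s) and ``N_eff`` the effective projection number:
``N_p / p`` for a helical scan (one pitch of travel) and ``N_p / 2`` for a
standard 180-degree scan.  Because the dose rate is measured in front of
the detector centre where the beam is strongest, this is the approximate
*maximum* surface entry dose.

Planned scans are compared by ratio scaling from a measured reference —
``dose_scale`` — which never requires knowing the absolute full-flux rate.

A published low-dose figure may instead quote ``rate * dt * N_p`` (all
acquired projections, no pitch division); :func:`dose_as_published` computes
that convention explicitly and reports the discrepancy with the per-pitch
rule so the two are never silently mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

from .errors import GeometryError, ModeError

__all__ = [
    "DoseModel",
    "effective_projections",
    "surface_entry_dose",
    "dose_scale",
    "dose_as_published",
]


def effective_projections(mode: str, n_proj: int, pitch: Optional[float] = None) -> float:
    """``N_p / p`` (helical) or ``N_p / 2`` (standard)."""
    if mode == "helical":
        if pitch is None or pitch <= 0:
            raise GeometryError("helical dose needs a positive pitch")
        return n_proj / pitch
    if mode == "standard":
        return n_proj / 2.0
    raise ModeError(f"unknown mode {mode!r}")


@dataclass
class DoseModel:
    """Dose-rate and exposure bookkeeping for one scan configuration."""

    rate_gy_s: float
    exposure_s: float
    n_proj: int
    mode: str = "helical"
    pitch: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rate_gy_s <= 0 or self.exposure_s <= 0 or self.n_proj <= 0:
            raise GeometryError("rate, exposure and projection count must be positive")
        # validates mode/pitch eagerly
        effective_projections(self.mode, self.n_proj, self.pitch)

    @property
    def n_effective(self) -> float:
        return effective_projections(self.mode, self.n_proj, self.pitch)


def surface_entry_dose(model: DoseModel) -> float:
    """Approximate maximum surface entry dose in Gy."""
    return model.rate_gy_s * model.exposure_s * model.n_effective


def dose_scale(
    reference_dose: float,
    reference: dict,
    target: dict,
    same_energy: bool = True,
) -> float:
    """Scale a measured dose to a different scan configuration.

    ``reference`` and ``target`` are dicts with keys ``exposure_s``,
    ``n_proj``, ``mode`` and (helical) ``pitch``:

        D_target = D_ref * (dt_t / dt_r) * (N_eff,t / N_eff,r)

    Scaling across photon energies is flagged (the measured rate changes
    with energy, so the ratio is no longer exact).
    """
    if reference_dose <= 0:
        raise GeometryError("reference dose must be positive")
    if not same_energy:
        warnings.warn(
            "scaling a dose across photon energies: the measured dose rate "
            "differs with energy, treat the result as indicative only",
            stacklevel=2,
        )

    def neff(cfg: dict) -> float:
        return effective_projections(
            cfg.get("mode", "helical"), cfg["n_proj"], cfg.get("pitch")
        )

    ratio = (target.get("exposure_s", reference.get("exposure_s", 1.0))
             / reference.get("exposure_s", 1.0))
    return reference_dose * ratio * neff(target) / neff(reference)


def dose_as_published(rate_gy_s: float, exposure_s: float, n_proj: int) -> float:
    """Total dose under the as-published low-dose convention,
    ``rate * dt * N_p`` — all acquired projections, without the per-pitch
    division of the effective-projection rule.  For a helical scan at pitch
    p this exceeds the per-pitch figure by the factor p."""
    if rate_gy_s <= 0 or exposure_s <= 0 or n_proj <= 0:
        raise GeometryError("rate, exposure and projection count must be positive")
    return rate_gy_s * exposure_s * n_proj
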