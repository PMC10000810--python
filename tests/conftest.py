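"""Shared fixtures: small simulated scans reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import helict
from helict.simulate import make_scaffold_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_helical_geometry():
    """Integer-v helical geometry (p = 2, v = 1) for exact round trips."""
    return helict.ScanGeometry(
        mode="helical",
        pixel_mm=0.013,
        n_rows=32,
        n_cols=64,
        n_proj=64,
        n_rot=2,
        pitch=2.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_helical_geometry):
    g = small_helical_geometry
    return make_scaffold_phantom(
        strand_diameter_mm=0.065,
        spacing_mm=0.13,
        block_mm=(0.35, 0.35, 1.0),
        voxel_mm=g.pixel_mm,
        height_mm=g.n_virtual_rows * g.pixel_mm,
        container_radius_mm=0.36,
        n_xy=g.n_cols,
    )


@pytest.fixture(scope="session")
def roundtrip_scans(small_helical_geometry, small_phantom):
    """Defect-free noise-free helical + standard scans of the same phantom."""
    g = small_helical_geometry
    scan_h = helict.simulate_scan(small_phantom, g)
    scan_s = helict.simulate_scan(small_phantom, g.as_standard())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        virt = helict.convert(scan_h.projections)
    return {"helical": scan_h, "standard": scan_s, "virtual": virt}


@pytest.fixture(scope="session")
def ring_results():
    """The helical-vs-standard matched-defect ring comparison (headline run)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return helict.ring_comparison_experiment(seed=1)
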