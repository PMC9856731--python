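"""Shared fixtures.

The expensive artifacts — a desk-scale (2 mm) synthetic subject with all
24 coil placements solved — are built once per session and shared across
the mapping, dose-response and evaluation tests.  Oracle-style solver and
coil tests build their own tiny models instead.
"""

from __future__ import annotations

import numpy as np
import pytest

import tmsmap
from tmsmap import HeadGeometry, MEPGenConfig
from tmsmap.dose_response import calibrate_sigmoid_truth, simulate_meps
from tmsmap.pipeline import solve_all_placements


@pytest.fixture(scope="session")
def subject2mm():
    """Default synthetic subject at desk resolution (2 mm voxels)."""
    return tmsmap.build_synthetic_head(HeadGeometry(voxel_size_mm=2.0), seed=1)


@pytest.fixture(scope="session")
def placements24(subject2mm):
    """The 24-placement sulcus-aligned protocol grid."""
    return tmsmap.placement_grid(
        subject2mm.sulcus_scalp_polyline(), projector=subject2mm.scalp_project
    )


@pytest.fixture(scope="session")
def maps100(subject2mm, placements24):
    """Cortical EF maps of all 24 placements at 100 %MSO."""
    return solve_all_placements(subject2mm, placements24)


@pytest.fixture(scope="session")
def calibrated_subject(subject2mm, maps100):
    calibrate_sigmoid_truth(subject2mm, maps100)
    return subject2mm


@pytest.fixture(scope="session")
def records_noisy(calibrated_subject, maps100):
    """Trial-level MEPs under the study noise conditions (sigma 0.3)."""
    cfg = MEPGenConfig(
        sigmoid_truth=calibrated_subject.sigmoid_truth, noise_sigma_log=0.3, seed=1
    )
    return simulate_meps(calibrated_subject, maps100, cfg)


@pytest.fixture(scope="session")
def records_noisefree(calibrated_subject, maps100):
    """Noise-free MEPs (pure sigmoid of the field at the truth sites)."""
    cfg = MEPGenConfig(
        sigmoid_truth=calibrated_subject.sigmoid_truth,
        noise_sigma_log=0.0,
        noise_floor_mv=0.0,
        seed=1,
    )
    return simulate_meps(calibrated_subject, maps100, cfg)


@pytest.fixture(scope="session")
def flat_patch():
    """Small analytic surface patch with uniform vertex areas.

    A regular triangulated grid in the z=0 plane with normals +z; handy
    for exact hotspot-algebra assertions.
    """
    n = 6
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(n * n)], axis=1)
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris.append([a, a + 1, a + n])
            tris.append([a + 1, a + n + 1, a + n])
    tris = np.array(tris, dtype=np.int64)
    from tmsmap.head import CorticalSurface, _vertex_areas

    return CorticalSurface(
        vertices=verts,
        triangles=tris,
        vertex_normals=np.tile([0.0, 0.0, 1.0], (n * n, 1)),
        vertex_area_mm2=_vertex_areas(verts, tris),
    )
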