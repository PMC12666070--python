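"""Shared fixtures: phantoms, simple meshes, and cached benchmark pairs."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from c2pbench.geometry import TriangleMesh
from c2pbench.phantom import make_liver_phantom
from c2pbench.synthesis import GenerationConfig, generate_pair


@pytest.fixture(scope="session")
def phantom() -> TriangleMesh:
    return make_liver_phantom(seed=0, width=200.0)


@pytest.fixture(scope="session")
def phantom_b() -> TriangleMesh:
    return make_liver_phantom(seed=1, width=200.0)


@pytest.fixture(scope="session")
def default_pair(phantom):
    """One pair at the full default conditions (deformation, noise, 45 deg)."""
    return generate_pair(phantom, GenerationConfig(), seed=42)


@pytest.fixture(scope="session")
def clean_pair(phantom):
    """Zero-deformation, zero-noise pair at full perturbation magnitude."""
    cfg = GenerationConfig(deform_max=0.0, noise_sigma=0.0)
    return generate_pair(phantom, cfg, seed=7)


@pytest.fixture(scope="session")
def recovery_pair(phantom):
    """Zero-deformation, zero-noise pair with a small (in-basin) perturbation."""
    cfg = GenerationConfig(
        deform_max=0.0, noise_sigma=0.0, rot_max=2.0, trans_max=2.0
    )
    return generate_pair(phantom, cfg, seed=3)


@pytest.fixture(scope="session")
def bar_mesh() -> TriangleMesh:
    """Subdivided box bar (100 x 20 x 20 mm) for deformation tests."""
    box = trimesh.creation.box(extents=(100.0, 20.0, 20.0))
    v, f = box.vertices, box.faces
    for _ in range(3):
        v, f = trimesh.remesh.subdivide(v, f)
    return TriangleMesh(np.asarray(v), np.asarray(f))


@pytest.fixture(scope="session")
def ellipsoid_mesh() -> TriangleMesh:
    """Left-right symmetric ellipsoid (icosphere stretched along x)."""
    sphere = trimesh.creation.icosphere(subdivisions=3)
    v = np.asarray(sphere.vertices) * np.array([2.0, 1.0, 1.0]) * 50.0
    return TriangleMesh(v, np.asarray(sphere.faces))
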