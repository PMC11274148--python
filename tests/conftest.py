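"""Shared fixtures: generated geometries and fields are session-scoped since
construction is deterministic and reused by many tests."""

import numpy as np
import pytest

from dissectwall.core import REGION_TO_ID, Centerline, LabeledSurfaceMesh
from dissectwall.pulsatile_flow import FlowWaveform, FluidProperties
from dissectwall.synthetic_cohort import (
    DissectionParams,
    FieldConfig,
    build_dissected_geometry,
    synthesize_fields,
)


@pytest.fixture(scope="session")
def props():
    return FluidProperties()


@pytest.fixture(scope="session")
def waveform():
    return FlowWaveform.default()


@pytest.fixture(scope="session")
def default_params():
    return DissectionParams(seed=7)


@pytest.fixture(scope="session")
def coarse_params():
    """Cheap mesh for multi-patient loops."""
    return DissectionParams(seed=7, n_theta=32, ring_spacing=6.0)


@pytest.fixture(scope="session")
def geometry(default_params):
    return build_dissected_geometry(default_params)


@pytest.fixture(scope="session")
def fields(geometry, waveform, props, default_params):
    mesh, centerline, _ = geometry
    return synthesize_fields(
        mesh, waveform, props, default_params, FieldConfig(), centerline=centerline
    )


@pytest.fixture(scope="session")
def clean_fields(waveform, props):
    """Noise-free, reversal-free fields: every vertex should have OSI = 0."""
    params = DissectionParams(seed=3, noise_sd=0.0, n_theta=32, ring_spacing=6.0)
    mesh, centerline, tear = build_dissected_geometry(params)
    wss, planes = synthesize_fields(
        mesh, waveform, props, params, FieldConfig(fl_oscillation=0.0), centerline=centerline
    )
    return mesh, wss, planes


def make_cylinder(radius=15.0, length=100.0, n_theta=64, n_rings=21, label="TL"):
    """Straight z-aligned open tube, uniformly labeled; used as a no-flap fixture."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0.0, length, n_rings)
    verts = []
    for zz in z:
        verts.append(np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.full(n_theta, zz)]))
    verts = np.concatenate(verts)
    tris = []
    for i in range(n_rings - 1):
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            a, b = i * n_theta, (i + 1) * n_theta
            tris.append((a + k, b + k, a + k2))
            tris.append((b + k, b + k2, a + k2))
    mesh = LabeledSurfaceMesh(
        vertices=verts,
        triangles=np.asarray(tris),
        vertex_region=np.full(len(verts), REGION_TO_ID[label]),
        vertex_axial=np.tile([0.0, 0.0, 1.0], (len(verts), 1)),
    )
    centerline = Centerline(points=np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
    centerline.markers = {"descending": (0.0, length), "dissected": (0.0, length)}
    return mesh, centerline
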