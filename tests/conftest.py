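"""Shared fixtures: analytic meshes, patches, and a reference submission."""

from __future__ import annotations

import numpy as np
import pytest

from aneuvar.hemodynamics import BloodProperties, compute_submission
from aneuvar.io_formats import CrossSectionPatch, SurfaceMesh
from aneuvar.synthetic import ReferenceCase, _disc, _sphere, _tube, make_reference


def tube_mesh(radius=1.225, length=20.0, n_circ=128, n_ax=160,
              fields=None) -> SurfaceMesh:
    pts, tris = _tube(radius, 0.0, length, n_circ, n_ax)
    return SurfaceMesh(pts, tris, fields or {})


def sphere_mesh(radius=1.0, n_theta=24, n_phi=48, center=(0.0, 0.0, 0.0)):
    pts, tris, cos_theta, _ = _sphere(np.asarray(center, float), radius,
                                      n_theta, n_phi)
    return SurfaceMesh(pts, tris, {}), cos_theta


def disc_patch(radius=1.225, vbar=49.0, n_r=16, n_phi=64,
               magnitude_only=False, normal=(1.0, 0.0, 0.0),
               center=(0.0, 0.0, 0.0), profile="poiseuille"):
    """Disc cross-section carrying an axial parabolic (or plug) profile."""
    pts, tris, rho = _disc(np.asarray(center, float), normal, radius, n_r, n_phi)
    if profile == "poiseuille":
        speed = 2.0 * vbar * (1.0 - (rho / radius) ** 2)
    else:
        speed = np.full_like(rho, vbar)
    if magnitude_only:
        vel = np.abs(speed)
    else:
        vel = speed[:, None] * np.asarray(normal, float)[None, :]
    return CrossSectionPatch(pts, tris, normal, vel,
                             is_magnitude_only=magnitude_only)


@pytest.fixture(scope="session")
def reference_submission():
    return make_reference(ReferenceCase())


@pytest.fixture(scope="session")
def reference_result(reference_submission):
    sub = reference_submission
    props = BloodProperties(density=sub.meta.density,
                            viscosity=sub.meta.viscosity)
    return compute_submission(sub.mesh, sub.sections, sub.regions, props,
                              meta=sub.meta)
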