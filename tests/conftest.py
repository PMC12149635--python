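"""Shared fixtures: phantoms and derived pipeline products.

Expensive phantoms are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from meniscovasc.phantom import PhantomSpec, generate_phantom
from meniscovasc.segmentation import segment_vasculature
from meniscovasc.zonation import build_zone_map

STRAIGHT_ANGLES = (20.0, 45.0, 90.0, 135.0, 160.0)


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free phantom of 5 non-touching straight radial tubes."""
    spec = PhantomSpec(n_trees=5, tree_mode="straight",
                       tree_angles_deg=STRAIGHT_ANGLES, noise_sd=0.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def straight_zones(straight_phantom):
    spec, _, truth = straight_phantom
    return build_zone_map(truth.organ_mask, margin_um=spec.margin_um,
                          spacing_um=spec.spacing_um)


@pytest.fixture(scope="session")
def arborized_phantom():
    """Noise-free default (branching-tree) phantom."""
    spec = PhantomSpec(noise_sd=0.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def annulus_mask():
    """Ideal constant-height half-annulus (inner 40, outer 70 voxels) plus
    the analytic radius/angle fields needed for closed-form zone rules."""
    nz, ny, nx = 24, 161, 92
    cy, cx = 80.0, 10.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r = np.hypot(yy - cy, xx - cx)
    th = np.degrees(np.arctan2(yy - cy, xx - cx))
    proj = (r >= 40) & (r <= 70) & (th >= -90) & (th <= 90)
    organ = np.broadcast_to(proj, (nz, ny, nx)).copy()
    return {"organ": organ, "r": r, "theta": th, "proj": proj,
            "inner": 40.0, "outer": 70.0, "center": (cy, cx)}
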