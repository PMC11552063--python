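"""Shared fixtures: synthetic scenes and straight-vessel factories.

Scenes are session-scoped because rendering a full 768x768 scene takes a
noticeable fraction of a second and every scene is deterministic anyway.
"""

from __future__ import annotations

import numpy as np
import pytest

from slovasc import synthetic_data as sd


@pytest.fixture(scope="session")
def macula_scene():
    """Low-noise macula-centered scene (right eye) with ground truth."""
    spec = sd.default_scene_spec(
        location="macula", laterality="right", seed=3, noise_sd=2.0
    )
    return sd.generate_scene(spec)


@pytest.fixture(scope="session")
def disc_scene():
    """Low-noise disc-centered scene (right eye) with ground truth."""
    spec = sd.default_scene_spec(
        location="disc", laterality="right", seed=5, noise_sd=2.0
    )
    return sd.generate_scene(spec)


def straight_vessel(width: float, length: float = 600.0, vertical: bool = False):
    """Render one straight vessel; even widths sit on half-integer centers so
    the drawn caliber equals the nominal width.  Returns (mask, shape)."""
    off = 0.5 if int(round(width)) % 2 == 0 else 0.0
    lo = 40.0 + off
    if vertical:
        verts = [(20.0, lo), (20.0 + length, lo)]
        shape = (int(length) + 40, 81)
    else:
        verts = [(lo, 20.0), (lo, 20.0 + length)]
        shape = (81, int(length) + 40)
    curve = sd.VesselCurve(
        kind="polyline", width_px=width, vessel_class="vein", vertices=verts
    )
    return sd.render_vessel(curve, width, shape), shape


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
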