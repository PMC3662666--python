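"""Shared fixtures: a small ideal-helix protein and perceived ring poses."""

from __future__ import annotations

import numpy as np
import pytest

from csprobe.structio import perceive_aromatic_rings
from csprobe.synthfix import FixtureSpec, make_helix_protein, make_ring_pose


@pytest.fixture(scope="session")
def helix_spec() -> FixtureSpec:
    return FixtureSpec(n_residues=20, seed=11)


@pytest.fixture(scope="session")
def helix20(helix_spec):
    """20-residue ideal helix with built amide protons."""
    return make_helix_protein(helix_spec)


@pytest.fixture(scope="session")
def benzene_pose(helix_spec, helix20):
    """Single benzene ring 4 A from the middle residue's amide proton, perceived."""
    return perceive_aromatic_rings(make_ring_pose(helix_spec, helix20))


@pytest.fixture(scope="session")
def benzene_ring(benzene_pose):
    return benzene_pose.rings[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def ideal_benzene(center=(0.0, 0.0, 0.0), radius: float = 1.39) -> np.ndarray:
    """Regular hexagon in the xy-plane (CCW about +z)."""
    angles = np.radians(np.arange(0, 360, 60))
    ring = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1
    )
    return ring + np.asarray(center, float)
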