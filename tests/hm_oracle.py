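"""Independent brute-force Haigh-Mallion evaluator used as a test oracle.

Deliberately shares no code with the package: the ring plane comes from the
Newell polygon normal, projection goes through an explicit in-plane 2D basis,
and each per-bond triangle area is computed with the 2D shoelace formula.
Valid for exactly planar rings (which the fixtures construct), where the
Newell plane and any least-squares plane coincide.
"""

from __future__ import annotations

import numpy as np


def newell_normal(coords: np.ndarray) -> np.ndarray:
    """Polygon normal by Newell's method (right-handed w.r.t. vertex order)."""
    n = np.zeros(3)
    m = len(coords)
    for i in range(m):
        p, q = coords[i], coords[(i + 1) % m]
        n[0] += (p[1] - q[1]) * (p[2] + q[2])
        n[1] += (p[2] - q[2]) * (p[0] + q[0])
        n[2] += (p[0] - q[0]) * (p[1] + q[1])
    return n / np.linalg.norm(n)


def brute_force_shift(
    proton: np.ndarray,
    ring_coords: np.ndarray,
    intensity: float,
    target_factor_b: float,
) -> float:
    """Ring-current shift by explicit per-bond triangle construction."""
    proton = np.asarray(proton, float)
    ring_coords = np.asarray(ring_coords, float)
    center = ring_coords.mean(axis=0)
    normal = newell_normal(ring_coords)

    # explicit 2D basis in the ring plane
    e1 = ring_coords[1] - ring_coords[0]
    e1 = e1 - np.dot(e1, normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    def to2d(x: np.ndarray) -> tuple[float, float]:
        d = x - center
        return float(np.dot(d, e1)), float(np.dot(d, e2))

    px, py = to2d(proton)
    m = len(ring_coords)
    total = 0.0
    for i in range(m):
        j = (i + 1) % m
        ax, ay = to2d(ring_coords[i])
        bx, by = to2d(ring_coords[j])
        # shoelace signed area of triangle (p, a, b), CCW positive about normal
        area = 0.5 * ((ax - px) * (by - py) - (bx - px) * (ay - py))
        ri = float(np.linalg.norm(ring_coords[i] - proton))
        rj = float(np.linalg.norm(ring_coords[j] - proton))
        total += area * (1.0 / ri**3 + 1.0 / rj**3)
    return -intensity * target_factor_b * total


def random_planar_ring(rng: np.random.Generator, n_atoms: int = 6) -> np.ndarray:
    """Random exactly-planar convex-ish ring: jittered regular polygon,
    randomly oriented and translated."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_atoms))
    # keep vertices distinct and in convex position
    radii = rng.uniform(1.2, 1.6, n_atoms)
    flat = np.stack(
        [radii * np.cos(angles), radii * np.sin(angles), np.zeros(n_atoms)], axis=1
    )
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return flat @ q.T + rng.uniform(-10, 10, 3)
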