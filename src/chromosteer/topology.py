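"""Polymer topology diagnostics: Gauss linking number for closed curves.

Uses the exact solid-angle expression for polygonal segment pairs
(Klenin & Langowski, Biopolymers 2000, method 1a), so the linking number of
two disjoint closed polygons is an exact integer up to floating-point
rounding.  Used as a test-only check that dynamics never let chains cross.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gauss_linking_number", "make_ring", "interlinked_rings"]


def _segment_pair_solid_angle(p1, p2, p3, p4) -> float:
    """Signed solid-angle contribution of segments p1->p2 and p3->p4."""
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2

    def unit_cross(a, b):
        c = np.cross(a, b)
        n = np.linalg.norm(c)
        return c / n if n > 1e-14 else None

    n1 = unit_cross(r13, r14)
    n2 = unit_cross(r14, r24)
    n3 = unit_cross(r24, r23)
    n4 = unit_cross(r23, r13)
    if n1 is None or n2 is None or n3 is None or n4 is None:
        return 0.0  # coplanar degenerate pair contributes nothing

    def asin_dot(a, b):
        return np.arcsin(np.clip(np.dot(a, b), -1.0, 1.0))

    omega = (
        asin_dot(n1, n2) + asin_dot(n2, n3) + asin_dot(n3, n4) + asin_dot(n4, n1)
    )
    sign = np.sign(np.dot(np.cross(p4 - p3, p2 - p1), r13))
    return float(omega * sign)


def gauss_linking_number(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Linking number of two closed polygonal curves.

    The curves are closed implicitly (last vertex connects to the first).
    Returns a float that should round to an integer for disjoint curves.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise ValueError("curves must be (n, 3) vertex arrays")
    total = 0.0
    na, nb = len(a), len(b)
    for i in range(na):
        p1, p2 = a[i], a[(i + 1) % na]
        for j in range(nb):
            p3, p4 = b[j], b[(j + 1) % nb]
            total += _segment_pair_solid_angle(p1, p2, p3, p4)
    return total / (4.0 * np.pi)


def make_ring(
    n_beads: int,
    radius: float | None = None,
    center: np.ndarray | None = None,
    normal: np.ndarray | None = None,
    bond_length: float = 0.97,
) -> np.ndarray:
    """Planar circular ring of beads with the requested bond length."""
    if radius is None:
        radius = bond_length / (2.0 * np.sin(np.pi / n_beads))
    t = np.linspace(0.0, 2.0 * np.pi, n_beads, endpoint=False)
    ring = np.stack([radius * np.cos(t), radius * np.sin(t),
                     np.zeros(n_beads)], axis=1)
    if normal is not None:
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, normal)
        s = np.linalg.norm(v)
        if s > 1e-12:
            c = np.dot(z, normal)
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
            ring = ring @ rot.T
    if center is not None:
        ring = ring + np.asarray(center, dtype=float)
    return ring


def interlinked_rings(n_beads: int = 20, bond_length: float = 0.97):
    """Two rings interlinked like chain links (linking number +-1)."""
    r1 = make_ring(n_beads, bond_length=bond_length)
    radius = bond_length / (2.0 * np.sin(np.pi / n_beads))
    # second ring in the xz-plane, centered on the first ring's rim, so the
    # first ring threads its disk transversally (Hopf link)
    r2 = make_ring(
        n_beads,
        bond_length=bond_length,
        center=np.array([radius, 0.0, 0.0]),
        normal=np.array([0.0, 1.0, 0.0]),
    )
    return r1, r2
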