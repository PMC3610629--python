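"""Coarse-grained bead-spring chromosome model.

Chains of beads interact through FENE bonds, a discrete worm-like-chain
(Kratky-Porod) bending term, and purely repulsive (WCA) excluded volume
acting on all bead pairs, intra- and inter-chain.  Internally everything is
in reduced units: bead diameter sigma = 1, kT = 1, bead mass = 1.  The
nm/bp calibration (30 nm and 10 kb per bead by default) only enters at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import WCA_CUT, compute_forces

__all__ = [
    "ForceFieldParams",
    "SystemState",
    "box_side_for_volume_fraction",
    "potential_energy",
    "forces",
    "build_mitotic",
    "build_random_walk",
    "place_chains",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants; physical fields are informational metadata,
    the simulation runs on the reduced-unit fields."""

    sigma_nm: float = 30.0
    bp_per_bead: int = 10_000
    persistence_length_nm: float = 150.0
    fene_k: float = 30.0        # kT / sigma^2
    fene_R0: float = 1.5        # sigma
    lj_epsilon: float = 1.0     # kT
    kT: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_nm", "persistence_length_nm", "fene_k",
                     "fene_R0", "lj_epsilon", "kT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fene_R0 <= 1.0:
            raise ValueError("fene_R0 must exceed the bead diameter")

    @property
    def bend_k(self) -> float:
        """Kratky-Porod stiffness (kT): persistence length in bead units."""
        return self.persistence_length_nm / self.sigma_nm * self.kT

    @property
    def kuhn_length_bp(self) -> float:
        """Kuhn length (2 x persistence length) expressed in bp."""
        return 2.0 * self.persistence_length_nm / self.sigma_nm * self.bp_per_bead


class FeneOverstretchError(RuntimeError):
    """A bond reached the FENE divergence radius: topology violated."""


@dataclass
class SystemState:
    """Multi-chain bead conformation in a periodic cubic box.

    Positions are stored concatenated; ``chain_starts`` delimits chains.
    ``closed`` marks ring chains (extra closing bond and wrapped angles).
    Positions are kept unwrapped; all interactions use minimum image.
    """

    pos: np.ndarray                      # (N, 3), sigma units
    chain_starts: np.ndarray             # (n_chains + 1,)
    box_side: float
    vel: np.ndarray | None = None
    closed: np.ndarray | None = None     # (n_chains,) bool
    periodic: bool = True
    time: float = 0.0
    _bonds: np.ndarray | None = field(default=None, repr=False)
    _angles: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.chain_starts = np.asarray(self.chain_starts, dtype=np.int64)
        if self.vel is None:
            self.vel = np.zeros_like(self.pos)
        else:
            self.vel = np.ascontiguousarray(self.vel, dtype=np.float64)
        if self.closed is None:
            self.closed = np.zeros(self.n_chains, dtype=bool)
        else:
            self.closed = np.asarray(self.closed, dtype=bool)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.chain_starts) - 1

    @property
    def chains(self) -> list[np.ndarray]:
        return [
            self.pos[self.chain_starts[c]:self.chain_starts[c + 1]]
            for c in range(self.n_chains)
        ]

    @property
    def chain_id(self) -> np.ndarray:
        cid = np.empty(self.n_beads, dtype=np.int64)
        for c in range(self.n_chains):
            cid[self.chain_starts[c]:self.chain_starts[c + 1]] = c
        return cid

    def topology(self) -> tuple[np.ndarray, np.ndarray]:
        """Bond (B, 2) and angle (A, 3) index arrays, cached."""
        if self._bonds is None:
            bonds, angles = [], []
            for c in range(self.n_chains):
                s, e = self.chain_starts[c], self.chain_starts[c + 1]
                n = e - s
                for i in range(s, e - 1):
                    bonds.append((i, i + 1))
                if self.closed[c] and n > 2:
                    bonds.append((e - 1, s))
                    for i in range(n):
                        angles.append((s + (i - 1) % n, s + i, s + (i + 1) % n))
                else:
                    for i in range(s + 1, e - 1):
                        angles.append((i - 1, i, i + 1))
            self._bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
            self._angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
        return self._bonds, self._angles

    def copy(self) -> "SystemState":
        new = SystemState(
            self.pos.copy(), self.chain_starts.copy(), self.box_side,
            vel=self.vel.copy(), closed=self.closed.copy(),
            periodic=self.periodic, time=self.time,
        )
        new._bonds, new._angles = self._bonds, self._angles
        return new


def box_side_for_volume_fraction(
    n_beads_total: int, sigma: float = 1.0, phi: float = 0.10
) -> float:
    """Cubic box side giving bead volume fraction ``phi``."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    return (n_beads_total * (np.pi / 6.0) * sigma ** 3 / phi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def _kernel_args(state: SystemState, params: ForceFieldParams,
                 f_cap: float = 0.0, r_cap: float = 0.0, u_cap: float = 0.0):
    bonds, angles = state.topology()
    box = state.box_side if state.periodic else -1.0
    return (
        state.pos, state.chain_id, bonds, angles, box,
        params.fene_k, params.fene_R0, params.bend_k, params.lj_epsilon,
        f_cap, r_cap, u_cap,
    )


def forces_and_energy(
    state: SystemState, params: ForceFieldParams,
    f_cap: float = 0.0, r_cap: float = 0.0, u_cap: float = 0.0,
) -> tuple[np.ndarray, dict[str, float]]:
    f, e_fene, e_bend, e_intra, e_inter, err = compute_forces(
        *_kernel_args(state, params, f_cap, r_cap, u_cap)
    )
    if err:
        raise FeneOverstretchError(
            "a bond reached the FENE divergence radius "
            f"(R0 = {params.fene_R0}); reduce dt or relax the configuration"
        )
    terms = {
        "fene": e_fene, "bend": e_bend,
        "lj_intra": e_intra, "lj_inter": e_inter,
        "total": e_fene + e_bend + e_intra + e_inter,
    }
    return f, terms


def forces(state: SystemState, params: ForceFieldParams) -> np.ndarray:
    """Per-bead forces, -grad U (reduced units)."""
    return forces_and_energy(state, params)[0]


def potential_energy(
    state: SystemState, params: ForceFieldParams
) -> dict[str, float]:
    """Per-term potential energy via a plain-numpy reference path.

    This is an independent implementation used to cross-check the compiled
    kernel; both are exercised in the test suite.
    """
    box = state.box_side if state.periodic else None

    def mi(d):
        return d - box * np.round(d / box) if box else d

    pos = state.pos
    bonds, angles = state.topology()
    # FENE
    d = mi(pos[bonds[:, 1]] - pos[bonds[:, 0]])
    r2 = (d ** 2).sum(1)
    if np.any(r2 >= params.fene_R0 ** 2):
        raise FeneOverstretchError("bond length >= R0")
    e_fene = float(
        (-0.5 * params.fene_k * params.fene_R0 ** 2
         * np.log(1 - r2 / params.fene_R0 ** 2)).sum()
    )
    # bending
    e_bend = 0.0
    if len(angles):
        b1 = mi(pos[angles[:, 1]] - pos[angles[:, 0]])
        b2 = mi(pos[angles[:, 2]] - pos[angles[:, 1]])
        ct = (b1 * b2).sum(1) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
        )
        e_bend = float((params.bend_k * (1.0 - ct)).sum())
    # WCA over all pairs
    n = state.n_beads
    iu, ju = np.triu_indices(n, k=1)
    d = mi(pos[ju] - pos[iu])
    r2 = (d ** 2).sum(1)
    within = r2 < WCA_CUT ** 2
    inv6 = 1.0 / r2[within] ** 3
    u = 4.0 * params.lj_epsilon * (inv6 ** 2 - inv6) + params.lj_epsilon
    cid = state.chain_id
    same = cid[iu[within]] == cid[ju[within]]
    e_intra = float(u[same].sum())
    e_inter = float(u[~same].sum())
    return {
        "fene": e_fene, "bend": e_bend,
        "lj_intra": e_intra, "lj_inter": e_inter,
        "total": e_fene + e_bend + e_intra + e_inter,
    }


# ---------------------------------------------------------------------------
# initial conformations
# ---------------------------------------------------------------------------

def _resample_chordlength(path: np.ndarray, spacing: float) -> np.ndarray:
    """Greedy resampling of a dense polyline at constant *chord* length, so
    every emitted bond has length exactly ``spacing``."""
    out = [path[0]]
    last = path[0]
    k = 1
    while k < len(path):
        d = np.linalg.norm(path[k] - last)
        if d < spacing:
            k += 1
            continue
        # interpolate on segment (path[k-1], path[k]) to exact distance
        a, b = path[k - 1], path[k]
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(a + mid * (b - a) - last) < spacing:
                lo = mid
            else:
                hi = mid
        last = a + hi * (b - a)
        out.append(last)
    return np.array(out)


def _solenoid_path(
    n_loops: int, loop_radius: float, core_radius: float,
    turns_per_loop: float, pitch: float, pts_per_loop: int,
) -> np.ndarray:
    u = np.linspace(0.0, n_loops, n_loops * pts_per_loop, endpoint=False)
    phase = 2.0 * np.pi * turns_per_loop * u          # loop azimuth
    petal = np.pi * (u % 1.0)                         # 0 -> pi sweep per loop
    radial = core_radius + (loop_radius - core_radius) * np.sin(petal)
    # transverse lobe separates the outgoing and returning strands
    lobe = 0.35 * loop_radius * np.sin(2.0 * petal)
    x = radial * np.cos(phase) - lobe * np.sin(phase)
    y = radial * np.sin(phase) + lobe * np.cos(phase)
    z = pitch * u
    return np.stack([x, y, z], axis=1)


def build_mitotic(
    chain_length_beads: int,
    loop_length_beads: int = 20,
    loop_radius: float | None = None,
    turns_per_loop: float = 0.382,
    pitch: float = 0.35,
    bond_length: float = 0.97,
) -> np.ndarray:
    """Compact solenoid: radial loops arranged helicoidally about an axis.

    A smooth parametric curve (petal-shaped loops departing radially from a
    rising, rotating core) is resampled at constant chord length, so every
    bond is exactly ``bond_length`` by construction.  Successive loops
    advance by the golden angle (0.382 turns), which keeps neighbouring
    petals nearly overlap-free at a tight axial pitch.  Deterministic.
    """
    if loop_length_beads < 6:
        raise ValueError("loops need at least 6 beads")
    if loop_radius is None:
        loop_radius = loop_length_beads * bond_length / (2.0 * np.pi) * 1.6
    core_radius = 1.2
    pts_per_loop = loop_length_beads * 40
    n_loops = max(1, int(np.ceil(chain_length_beads / loop_length_beads)))
    while True:
        path = _solenoid_path(
            n_loops, loop_radius, core_radius, turns_per_loop, pitch,
            pts_per_loop,
        )
        beads = _resample_chordlength(path, bond_length)
        if len(beads) >= chain_length_beads:
            return beads[:chain_length_beads]
        n_loops += 1


def build_random_walk(
    chain_length_beads: int,
    seed: int | None = None,
    bond_length: float = 0.97,
    confine_radius: float | None = None,
) -> np.ndarray:
    """Freely-jointed chain with fixed bond length.

    Excluded-volume overlap is left for the push-off relaxation stage, so
    without confinement the closed-form FJC statistics (<R^2> = N b^2) hold
    exactly.  With ``confine_radius`` set, steps leaving the sphere are
    redrawn, yielding a compact, highly self-overlapping (and after
    push-off, highly entangled) coil of chromosome-like linear size.
    """
    rng = np.random.default_rng(seed)
    if confine_radius is None:
        steps = rng.normal(size=(chain_length_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        return np.vstack([np.zeros(3), np.cumsum(steps * bond_length, axis=0)])
    pos = np.zeros((chain_length_beads, 3))
    for k in range(1, chain_length_beads):
        while True:
            step = rng.normal(size=3)
            step *= bond_length / np.linalg.norm(step)
            cand = pos[k - 1] + step
            if np.linalg.norm(cand) <= confine_radius:
                pos[k] = cand
                break
    return pos


def place_chains(
    conformations: list[np.ndarray],
    box_side: float,
    seed: int | None = None,
    min_separation: float = 0.9,
    max_attempts: int = 2000,
) -> SystemState:
    """Randomly rotate/translate chains into the box without inter-chain
    overlap (all minimum-image pair distances >= ``min_separation``)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    n_conf = len(conformations)
    confs = [np.asarray(c, dtype=float) - np.asarray(c, dtype=float).mean(0)
             for c in conformations]
    # anchor strategies, escalating: fully random; jittered 3-D grid cells;
    # xy-grid columns with z-only rotations (suits elongated conformations).
    # Each strategy restarts the whole packing so early placements cannot
    # block the structured anchors.
    n3 = int(np.ceil(n_conf ** (1 / 3)))
    cell3 = box_side / n3
    grid3 = [
        (np.array([i, j, k]) + 0.5) * cell3
        for i in range(n3) for j in range(n3) for k in range(n3)
    ]
    n2 = int(np.ceil(np.sqrt(n_conf)))
    cell2 = box_side / n2
    grid2 = [
        np.array([(i + 0.5) * cell2, (j + 0.5) * cell2, 0.5 * box_side])
        for i in range(n2) for j in range(n2)
    ]
    per_chain = max(50, max_attempts // (3 * n_conf))

    def try_strategy(kind: str) -> list[np.ndarray] | None:
        placed: list[np.ndarray] = []
        for conf in confs:
            anchors = rng.permutation(len(grid3) if kind == "grid3"
                                      else len(grid2))
            done = False
            for attempt in range(per_chain):
                if kind == "random":
                    rot = Rotation.random(rng=rng).as_matrix()
                    shift = rng.random(3) * box_side
                elif kind == "grid3":
                    rot = Rotation.random(rng=rng).as_matrix()
                    base = grid3[anchors[attempt % len(grid3)]]
                    shift = base + (rng.random(3) - 0.5) * 0.3 * cell3
                else:  # columns
                    theta = rng.random() * 2 * np.pi
                    rot = Rotation.from_euler("z", theta).as_matrix()
                    base = grid2[anchors[attempt % len(grid2)]]
                    shift = base + np.array(
                        [0.0, 0.0, (rng.random() - 0.5) * box_side]
                    )
                trial = conf @ rot.T + shift
                if _no_overlap(trial, placed, box_side, min_separation):
                    placed.append(trial)
                    done = True
                    break
            if not done:
                return None
        return placed

    placed = None
    for kind in ("random", "grid3", "columns"):
        placed = try_strategy(kind)
        if placed is not None:
            break
    if placed is None:
        raise RuntimeError(
            "could not place chains without overlap; box too small"
        )
    lengths = [len(p) for p in placed]
    starts = np.concatenate([[0], np.cumsum(lengths)])
    return SystemState(np.vstack(placed), starts, box_side)


def _no_overlap(
    trial: np.ndarray, placed: list[np.ndarray], box: float, min_sep: float
) -> bool:
    for other in placed:
        d = trial[:, None, :] - other[None, :, :]
        d -= box * np.round(d / box)
        if ((d ** 2).sum(-1) < min_sep ** 2).any():
            return False
    return True


def radius_of_gyration(pos: np.ndarray) -> float:
    c = pos - pos.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def maxwell_boltzmann_velocities(
    n_beads: int, kT: float, rng: np.random.Generator
) -> np.ndarray:
    v = rng.normal(scale=np.sqrt(kT), size=(n_beads, 3))
    return v - v.mean(axis=0)
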