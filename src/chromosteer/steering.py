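"""Steered colocalization: gene->bead footprints, time-ramped harmonic
restraints between locus centers of mass, and the colocalization order
parameter Q (percent of restrained pairs within the contact cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import RunParams, Trajectory, run_langevin
from .network import CoregNetwork
from .polymer import ForceFieldParams, SystemState


@dataclass
class RestraintSchedule:
    """Per-chain cis restraints with linearly ramped stiffness.

    ``pairs`` holds (chain index, bead-index set A, bead-index set B)
    triples; bead indices are global (into the concatenated position
    array) and both sets must lie on the same chain copy.
    """

    pairs: list[tuple[int, np.ndarray, np.ndarray]]
    k0: float = 0.02
    k1: float = 2.0
    t_steer: float = 100.0
    rest_center: float = 0.0

    def __post_init__(self) -> None:
        if not self.k1 >= self.k0 > 0:
            raise ValueError("need k1 >= k0 > 0")
        if self.t_steer <= 0:
            raise ValueError("t_steer must be positive")
        canon = []
        for chain, a, b in self.pairs:
            a = np.asarray(a, dtype=np.int64)
            b = np.asarray(b, dtype=np.int64)
            if a.size == 0 or b.size == 0:
                raise ValueError("restraint bead sets must be non-empty")
            canon.append((int(chain), a, b))
        self.pairs = canon

    def stiffness(self, t: float) -> float:
        x = min(max(t / self.t_steer, 0.0), 1.0)
        return self.k0 + (self.k1 - self.k0) * x

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per restraint with bead sets as
        comma-joined index lists."""
        rows = [
            (chain, ",".join(map(str, a)), ",".join(map(str, b)))
            for chain, a, b in self.pairs
        ]
        return pd.DataFrame(rows, columns=["chain", "beads_a", "beads_b"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "RestraintSchedule":
        pairs = [
            (int(row.chain),
             np.array([int(x) for x in str(row.beads_a).split(",")]),
             np.array([int(x) for x in str(row.beads_b).split(",")]))
            for row in df.itertuples(index=False)
        ]
        return cls(pairs, **kwargs)

    def _flat(self) -> tuple[np.ndarray, ...]:
        """Cached flat index arrays for vectorized COM accumulation."""
        if not hasattr(self, "_flat_cache"):
            idx_a = np.concatenate([a for _, a, _ in self.pairs])
            pid_a = np.concatenate([
                np.full(len(a), p) for p, (_, a, _) in enumerate(self.pairs)
            ])
            w_a = np.concatenate([
                np.full(len(a), 1.0 / len(a)) for _, a, _ in self.pairs
            ])
            idx_b = np.concatenate([b for _, _, b in self.pairs])
            pid_b = np.concatenate([
                np.full(len(b), p) for p, (_, _, b) in enumerate(self.pairs)
            ])
            w_b = np.concatenate([
                np.full(len(b), 1.0 / len(b)) for _, _, b in self.pairs
            ])
            self._flat_cache = (idx_a, pid_a, w_a, idx_b, pid_b, w_b)
        return self._flat_cache


@dataclass
class SteeringReport:
    times: list[float] = field(default_factory=list)
    q: list[float] = field(default_factory=list)
    mean_distance: list[float] = field(default_factory=list)
    contact_cutoff: float = 4.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "Q_percent": self.q,
             "mean_pair_distance": self.mean_distance}
        )


# ---------------------------------------------------------------------------
# gene -> bead mapping
# ---------------------------------------------------------------------------

def map_genes_to_beads(
    starts: np.ndarray, ends: np.ndarray, bp_per_bead: int
) -> list[np.ndarray]:
    """Contiguous bead footprint per 0-based half-open genomic interval."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if np.any(ends <= starts):
        raise ValueError("intervals must be non-empty half-open [start, end)")
    out = []
    for s, e in zip(starts, ends):
        first = s // bp_per_bead
        last = (e - 1) // bp_per_bead
        out.append(np.arange(first, last + 1, dtype=np.int64))
    return out


def schedule_from_network(
    network: CoregNetwork,
    state: SystemState,
    bp_per_bead: int,
    k0: float = 0.02,
    k1: float = 2.0,
    t_steer: float = 100.0,
) -> RestraintSchedule:
    """Build cis restraints replicating each network edge on every chain copy.

    Gene footprints beyond a chain's length are clipped; edges whose
    footprint falls entirely off the chain are rejected.
    """
    footprints = map_genes_to_beads(network.starts, network.ends, bp_per_bead)
    pairs = []
    for c in range(state.n_chains):
        offset = int(state.chain_starts[c])
        n = int(state.chain_starts[c + 1]) - offset
        for i, j, _ in network.edges:
            fa = footprints[i][footprints[i] < n]
            fb = footprints[j][footprints[j] < n]
            if fa.size == 0 or fb.size == 0:
                raise ValueError(
                    f"edge ({i},{j}) maps outside the {n}-bead chain; "
                    "annotation and chain length are inconsistent"
                )
            pairs.append((c, fa + offset, fb + offset))
    return RestraintSchedule(pairs, k0=k0, k1=k1, t_steer=t_steer)


# ---------------------------------------------------------------------------
# restraint energetics
# ---------------------------------------------------------------------------

def _pair_com_vectors(
    pos: np.ndarray, schedule: RestraintSchedule, box_side: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """COM separation vectors (minimum image) and distances per pair."""
    idx_a, pid_a, w_a, idx_b, pid_b, w_b = schedule._flat()
    n = schedule.n_pairs
    com_a = np.zeros((n, 3))
    com_b = np.zeros((n, 3))
    np.add.at(com_a, pid_a, pos[idx_a] * w_a[:, None])
    np.add.at(com_b, pid_b, pos[idx_b] * w_b[:, None])
    vecs = com_b - com_a
    if box_side is not None:
        vecs -= box_side * np.round(vecs / box_side)
    dists = np.linalg.norm(vecs, axis=1)
    return vecs, dists


def restraint_energy_and_force(
    pos: np.ndarray,
    schedule: RestraintSchedule,
    t: float,
    box_side: float | None = None,
) -> tuple[np.ndarray, float]:
    """Harmonic COM restraint forces and total energy at time ``t``.

    U = 1/2 k(t) (d_COM - rest_center)^2 per pair; the COM-gradient force
    is shared equally among each set's member beads.
    """
    k = schedule.stiffness(t)
    forces = np.zeros_like(pos)
    vecs, dists = _pair_com_vectors(pos, schedule, box_side)
    safe = np.maximum(dists, 1e-12)
    dev = dists - schedule.rest_center
    energy = float(0.5 * k * (dev ** 2).sum())
    # force on COM of set B: -k * dev * unit(B - A); shared per member bead
    fvec = (-k * dev / safe)[:, None] * vecs
    fvec[dists < 1e-12] = 0.0
    idx_a, pid_a, w_a, idx_b, pid_b, w_b = schedule._flat()
    np.add.at(forces, idx_b, fvec[pid_b] * w_b[:, None])
    np.add.at(forces, idx_a, -fvec[pid_a] * w_a[:, None])
    return forces, energy


def colocalization_Q(
    pos: np.ndarray,
    schedule: RestraintSchedule,
    r_c: float = 4.0,
    box_side: float | None = None,
) -> float:
    """Percent of restrained pairs with COM distance <= r_c (all copies)."""
    if schedule.n_pairs == 0:
        raise ValueError("schedule has no pairs")
    _, dists = _pair_com_vectors(pos, schedule, box_side)
    return float(100.0 * np.mean(dists <= r_c))


# ---------------------------------------------------------------------------
# steered run
# ---------------------------------------------------------------------------

def run_steered(
    state: SystemState,
    params: ForceFieldParams,
    schedule: RestraintSchedule,
    run: RunParams,
    r_c: float = 4.0,
) -> tuple[Trajectory, SteeringReport]:
    """Langevin run with the ramped restraint hook; Q(t) at snapshot cadence."""
    box = state.box_side if state.periodic else None
    t0 = state.time
    report = SteeringReport(contact_cutoff=r_c)

    def hook(pos: np.ndarray, t: float) -> tuple[np.ndarray, float]:
        return restraint_energy_and_force(pos, schedule, t - t0, box_side=box)

    cadence = run.snapshot_every or max(1, run.n_steps // 50)
    run = RunParams(
        dt=run.dt, n_steps=run.n_steps, friction=run.friction,
        temperature=run.temperature, seed=run.seed,
        neighbor_skin=run.neighbor_skin, snapshot_every=cadence,
    )
    traj = run_langevin(state, params, run, force_hook=hook)
    for pos, t in zip(traj.frames, traj.times):
        _, dists = _pair_com_vectors(pos, schedule, box)
        report.times.append(t)
        report.q.append(float(100.0 * np.mean(dists <= r_c)))
        report.mean_distance.append(float(dists.mean()))
    return traj, report
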