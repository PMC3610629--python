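"""Constant-temperature Langevin dynamics and diagnostics.

Integration uses the BAOAB splitting of Langevin dynamics, which reduces
exactly to velocity Verlet when the friction is zero (NVE), so the same
loop serves thermostatted production runs and energy-conservation checks.
Runs are bit-wise reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .polymer import (
    ForceFieldParams,
    SystemState,
    forces_and_energy,
)

ForceHook = Callable[[np.ndarray, float], tuple[np.ndarray, float]]
"""Additive force contribution: (positions, time) -> (forces, energy)."""


@dataclass
class RunParams:
    dt: float = 0.01
    n_steps: int = 1000
    friction: float = 0.5        # 1/tau; 0 disables the thermostat
    temperature: float = 1.0     # kT
    seed: int = 0
    neighbor_skin: float = 0.3   # informational; cells rebuilt every step
    snapshot_every: int = 0      # 0: keep only the final frame

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.02:
            raise ValueError("dt must be in (0, 0.02] for stability")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be >= 0")


@dataclass
class Trajectory:
    frames: list[np.ndarray] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    def append(self, state: SystemState, record: dict) -> None:
        self.frames.append(state.pos.copy())
        self.times.append(state.time)
        self.log.append(record)


def kinetic_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature, kT units (mass = 1)."""
    n = state.n_beads
    return float((state.vel ** 2).sum() / (3.0 * n))


def run_langevin(
    state: SystemState,
    params: ForceFieldParams,
    run: RunParams,
    force_hook: ForceHook | None = None,
    cap_schedule: Callable[[int], float] | None = None,
) -> Trajectory:
    """Evolve ``state`` in place for ``run.n_steps`` BAOAB steps.

    ``force_hook`` adds external forces (steering restraints).
    ``cap_schedule`` maps the step index to a pair-force cap (<= 0 for full
    WCA); used by the push-off protocol.
    """
    rng = np.random.default_rng(run.seed)
    dt = run.dt
    gamma = run.friction
    kT = run.temperature
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(max(0.0, (1.0 - c1 * c1)) * kT)
    else:
        c1, c2 = 1.0, 0.0

    def cap_args(step: int) -> tuple[float, float, float]:
        if cap_schedule is None:
            return 0.0, 0.0, 0.0
        f_cap = cap_schedule(step)
        if f_cap <= 0.0:
            return 0.0, 0.0, 0.0
        r_cap = _wca_cap_radius(f_cap, params.lj_epsilon)
        return f_cap, r_cap, _wca_energy(r_cap, params.lj_epsilon)

    f, terms = forces_and_energy(state, params, *cap_args(0))
    if force_hook is not None:
        fh, _ = force_hook(state.pos, state.time)
        f = f + fh

    traj = Trajectory()

    def record(step: int, terms: dict) -> None:
        traj.append(state, {
            "step": step,
            "temperature": kinetic_temperature(state),
            **{k: v for k, v in terms.items()},
        })

    if run.snapshot_every:
        record(0, terms)
    half = 0.5 * dt
    for step in range(1, run.n_steps + 1):
        state.vel += half * f
        state.pos += half * state.vel
        if gamma > 0:
            state.vel *= c1
            state.vel += c2 * rng.standard_normal(state.vel.shape)
        state.pos += half * state.vel
        state.time += dt
        f, terms = forces_and_energy(state, params, *cap_args(step))
        if force_hook is not None:
            fh, eh = force_hook(state.pos, state.time)
            f = f + fh
            terms = {**terms, "restraint": eh, "total": terms["total"] + eh}
        state.vel += half * f
        if not np.all(np.isfinite(state.pos)):
            raise RuntimeError(f"non-finite coordinates at step {step}")
        if run.snapshot_every and step % run.snapshot_every == 0:
            record(step, terms)
    if not run.snapshot_every or run.n_steps % max(run.snapshot_every, 1) != 0:
        record(run.n_steps, terms)
    return traj


# ---------------------------------------------------------------------------
# push-off
# ---------------------------------------------------------------------------

def _wca_energy(r: float, eps: float) -> float:
    inv6 = 1.0 / r ** 6
    return 4.0 * eps * (inv6 ** 2 - inv6) + eps


def _wca_force(r: float, eps: float) -> float:
    return 24.0 * eps * (2.0 / r ** 13 - 1.0 / r ** 7)


def _wca_cap_radius(f_cap: float, eps: float) -> float:
    """Radius where the WCA force magnitude equals ``f_cap``."""
    cut = 2.0 ** (1.0 / 6.0)
    if f_cap <= 0 or _wca_force(0.7, eps) <= f_cap:
        return 0.0
    return brentq(lambda r: _wca_force(r, eps) - f_cap, 0.2, cut - 1e-9)


def pushoff_relax(
    state: SystemState,
    params: ForceFieldParams,
    n_steps: int = 5000,
    run: RunParams | None = None,
    f_cap_start: float = 2.0,
    f_cap_end: float = 2000.0,
    full_wca_fraction: float = 0.2,
) -> Trajectory:
    """Soft push-off: pair forces capped, cap ramped up, then full WCA.

    The cap rises geometrically from ``f_cap_start`` to ``f_cap_end`` over
    the first ``1 - full_wca_fraction`` of the steps; the remainder runs
    with the untruncated WCA so the final state carries no residual overlap
    and chains can no longer cross.
    """
    if run is None:
        run = RunParams(dt=0.005, friction=1.0, temperature=1.0, seed=0)
    run = RunParams(
        dt=run.dt, n_steps=n_steps, friction=run.friction,
        temperature=run.temperature, seed=run.seed,
        snapshot_every=run.snapshot_every,
    )
    ramp_steps = max(1, int(n_steps * (1.0 - full_wca_fraction)))
    log_f0, log_f1 = np.log(f_cap_start), np.log(f_cap_end)

    def cap_schedule(step: int) -> float:
        if step >= ramp_steps:
            return 0.0
        x = step / ramp_steps
        return float(np.exp(log_f0 + (log_f1 - log_f0) * x))

    return run_langevin(state, params, run, cap_schedule=cap_schedule)


# ---------------------------------------------------------------------------
# contact probability diagnostic
# ---------------------------------------------------------------------------

def contact_probability(
    frames: list[np.ndarray],
    chain_starts: np.ndarray,
    contact_cutoff: float = 2.0,
    box_side: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """P(s): fraction of intra-chain bead pairs at contour separation s
    within the cutoff, averaged over chains and frames."""
    chain_starts = np.asarray(chain_starts)
    n_chain = len(chain_starts) - 1
    max_len = int(np.max(np.diff(chain_starts)))
    hits = np.zeros(max_len)
    tot = np.zeros(max_len)
    cut2 = contact_cutoff ** 2
    for pos in frames:
        for c in range(n_chain):
            p = pos[chain_starts[c]:chain_starts[c + 1]]
            n = len(p)
            for s in range(1, n):
                d = p[s:] - p[:-s]
                if box_side is not None:
                    d -= box_side * np.round(d / box_side)
                r2 = (d ** 2).sum(1)
                hits[s] += (r2 < cut2).sum()
                tot[s] += len(r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_of_s = np.where(tot > 0, hits / tot, np.nan)
    s_vals = np.arange(max_len)
    return s_vals[1:], p_of_s[1:]


def log_binned_slope(
    s: np.ndarray,
    p: np.ndarray,
    s_min: float = 2.0,
    s_max: float | None = None,
    n_bins: int = 12,
) -> float:
    """Least-squares slope of log P(s) vs log s over log-spaced bins."""
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    if s_max is None:
        s_max = s.max()
    edges = np.geomspace(s_min, s_max, n_bins + 1)
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (s >= lo) & (s < hi) & np.isfinite(p) & (p > 0)
        if sel.any():
            xs.append(np.log10(np.sqrt(lo * hi)))
            ys.append(np.log10(p[sel].mean()))
    if len(xs) < 3:
        raise ValueError("not enough populated bins for a slope estimate")
    coef = np.polyfit(xs, ys, 1)
    return float(coef[0])
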