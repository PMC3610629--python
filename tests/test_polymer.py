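import numpy as np
import pytest
from scipy.spatial.distance import pdist

from chromosteer.polymer import (
    FeneOverstretchError,
    ForceFieldParams,
    SystemState,
    box_side_for_volume_fraction,
    build_mitotic,
    build_random_walk,
    forces_and_energy,
    place_chains,
    potential_energy,
    radius_of_gyration,
)


def random_two_chain_state(rng, n=10, box=8.0, spread=2.2, min_pair=0.85):
    """Small random 2-chain configuration with safe bond lengths and no
    pathologically close pair (keeps finite differences well conditioned)."""
    while True:
        chains = []
        for _ in range(2):
            steps = rng.normal(size=(n - 1, 3))
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            steps *= rng.uniform(0.9, 1.1, size=(n - 1, 1))
            start = rng.random(3) * spread
            chains.append(np.vstack([start, start + np.cumsum(steps, axis=0)]))
        pos = np.vstack(chains)
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(r, np.inf)
        if r.min() >= min_pair:
            return SystemState(pos, [0, n, 2 * n], box)


def numerical_forces(state, ff, beads, h=1e-4):
    """Fourth-order central-difference gradient of the total energy."""
    out = {}
    for bead in beads:
        g = np.zeros(3)
        for k in range(3):
            vals = []
            for c in (-2, -1, 1, 2):
                s = state.copy()
                s.pos[bead, k] += c * h
                vals.append(potential_energy(s, ff)["total"])
            em2, em1, ep1, ep2 = vals
            g[k] = -(em2 - 8 * em1 + 8 * ep1 - ep2) / (12 * h)
        out[bead] = g
    return out


class TestBoxSide:
    def test_closed_form_unit_case(self):
        assert box_side_for_volume_fraction(1, sigma=1.0, phi=np.pi / 6) == (
            pytest.approx(1.0)
        )

    def test_doubling_beads_scales_cube_root(self):
        l1 = box_side_for_volume_fraction(500)
        l2 = box_side_for_volume_fraction(1000)
        assert l2 / l1 == pytest.approx(2 ** (1 / 3))

    def test_hand_computed_production_case(self):
        # independent arithmetic: (6000 * pi/6 / 0.1)^(1/3)
        expect = (6000 * np.pi / 6.0 / 0.1) ** (1.0 / 3.0)
        assert box_side_for_volume_fraction(6 * 1000, phi=0.10) == (
            pytest.approx(expect)
        )

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            box_side_for_volume_fraction(10, phi=0.0)


class TestEnergy:
    def test_straight_chain_zero_bend(self, ff):
        n = 8
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 1.13  # outside the WCA cutoff
        state = SystemState(pos, [0, n], 50.0)
        terms = potential_energy(state, ff)
        assert terms["bend"] == pytest.approx(0.0, abs=1e-12)
        assert terms["lj_intra"] == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_bend_equals_bend_k(self, ff):
        pos = np.array([[0.0, 0, 0], [1.13, 0, 0], [1.13, 1.13, 0]])
        state = SystemState(pos, [0, 3], 50.0)
        terms = potential_energy(state, ff)
        assert terms["bend"] == pytest.approx(ff.bend_k)

    def test_kernel_matches_numpy_reference(self, ff, rng):
        for _ in range(5):
            state = random_two_chain_state(rng)
            _, terms_k = forces_and_energy(state, ff)
            terms_r = potential_energy(state, ff)
            for key in ("fene", "bend", "lj_intra", "lj_inter"):
                assert terms_k[key] == pytest.approx(terms_r[key], rel=1e-9)

    def test_overstretched_bond_raises(self, ff):
        pos = np.array([[0.0, 0, 0], [1.6, 0, 0]])
        state = SystemState(pos, [0, 2], 50.0)
        with pytest.raises(FeneOverstretchError):
            potential_energy(state, ff)
        with pytest.raises(FeneOverstretchError):
            forces_and_energy(state, ff)

    def test_translation_invariance_periodic(self, ff, rng):
        state = random_two_chain_state(rng)
        e1 = potential_energy(state, ff)["total"]
        shifted = state.copy()
        shifted.pos += rng.random(3) * 17.3
        e2 = potential_energy(shifted, ff)["total"]
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_rotation_invariance_nonperiodic(self, ff, rng):
        from scipy.spatial.transform import Rotation

        state = random_two_chain_state(rng)
        state.periodic = False
        e1 = potential_energy(state, ff)["total"]
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = state.copy()
        rotated.periodic = False
        rotated.pos = state.pos @ rot.T
        e2 = potential_energy(rotated, ff)["total"]
        assert e2 == pytest.approx(e1, rel=1e-9)


class TestForces:
    def test_dimer_equilibrium_zero_force(self, ff):
        # minimize the FENE+WCA bond numerically, then check force ~ 0
        from scipy.optimize import minimize_scalar

        def bond_u(r):
            u = -0.5 * ff.fene_k * ff.fene_R0 ** 2 * np.log(
                1 - (r / ff.fene_R0) ** 2)
            if r < 2 ** (1 / 6):
                inv6 = 1.0 / r ** 6
                u += 4 * ff.lj_epsilon * (inv6 ** 2 - inv6) + ff.lj_epsilon
            return u

        res = minimize_scalar(bond_u, bounds=(0.7, 1.3), method="bounded",
                              options={"xatol": 1e-12})
        r_eq = res.x
        pos = np.array([[0.0, 0, 0], [r_eq, 0, 0]])
        state = SystemState(pos, [0, 2], 50.0)
        f, _ = forces_and_energy(state, ff)
        assert np.abs(f).max() < 1e-5

    def test_newtons_third_law(self, ff, rng):
        for _ in range(5):
            state = random_two_chain_state(rng)
            f, _ = forces_and_energy(state, ff)
            scale = max(1.0, np.abs(f).max())
            assert np.abs(f.sum(axis=0)).max() / scale < 1e-9

    def test_forces_match_numerical_gradient(self, ff, rng):
        state = random_two_chain_state(rng)
        f, _ = forces_and_energy(state, ff)
        beads = rng.choice(state.n_beads, size=4, replace=False)
        for bead, num in numerical_forces(state, ff, beads).items():
            scale = max(1.0, np.abs(num).max())
            assert np.abs(f[bead] - num).max() / scale < 1e-6


class TestBuilders:
    def test_mitotic_bond_lengths_in_range(self):
        conf = build_mitotic(200)
        bl = np.linalg.norm(np.diff(conf, axis=0), axis=1)
        assert (bl > 0.8).all() and (bl < 1.2).all()

    def test_mitotic_no_hard_overlap(self):
        conf = build_mitotic(300, loop_length_beads=12)
        assert pdist(conf).min() > 0.7

    def test_mitotic_deterministic(self):
        assert np.array_equal(build_mitotic(150), build_mitotic(150))

    def test_mitotic_compact_vs_random_walk(self):
        rg_mit = radius_of_gyration(build_mitotic(300, loop_length_beads=12))
        rg_rw = np.mean([
            radius_of_gyration(build_random_walk(300, seed=s))
            for s in range(30)
        ])
        assert rg_mit < 0.75 * rg_rw

    def test_random_walk_fjc_statistics(self):
        n, b = 200, 0.97
        r2 = []
        for seed in range(50):
            conf = build_random_walk(n, seed=seed, bond_length=b)
            r2.append(((conf[-1] - conf[0]) ** 2).sum())
        expect = (n - 1) * b ** 2
        # <R^2> = N b^2 with relative SE sqrt(2/3/50) ~ 12%
        assert np.mean(r2) == pytest.approx(expect, rel=0.4)

    def test_random_walk_bond_lengths(self):
        conf = build_random_walk(100, seed=3)
        bl = np.linalg.norm(np.diff(conf, axis=0), axis=1)
        assert np.allclose(bl, 0.97)

    def test_random_walk_seeds_differ(self):
        assert not np.array_equal(build_random_walk(50, seed=1),
                                  build_random_walk(50, seed=2))

    def test_confined_walk_stays_inside(self):
        conf = build_random_walk(200, seed=5, confine_radius=5.0)
        assert np.linalg.norm(conf, axis=1).max() <= 5.0 + 1e-9


class TestPlacement:
    def test_single_chain_succeeds(self):
        conf = build_mitotic(60)
        state = place_chains([conf], 30.0, seed=0)
        assert state.n_chains == 1

    def test_dense_packing_rejected(self):
        confs = [build_mitotic(100) for _ in range(4)]
        with pytest.raises(RuntimeError, match="box too small"):
            place_chains(confs, 7.0, seed=0, max_attempts=300)

    def test_six_solenoids_at_ten_percent_no_overlap(self):
        n_beads, n_chains = 300, 6
        box = box_side_for_volume_fraction(n_beads * n_chains)
        confs = [build_mitotic(n_beads, loop_length_beads=12)
                 for _ in range(n_chains)]
        state = place_chains(confs, box, seed=0)
        # brute-force O(N^2) inter-chain scan with minimum image
        dmin = np.inf
        for a in range(n_chains):
            for b in range(a + 1, n_chains):
                d = state.chains[a][:, None, :] - state.chains[b][None, :, :]
                d -= box * np.round(d / box)
                dmin = min(dmin, np.sqrt((d ** 2).sum(-1)).min())
        assert dmin >= 0.9


def test_wlc_bond_correlation_decay(ff):
    """Thermalized single chain decorrelates over ~ the persistence length."""
    from chromosteer.engine import RunParams, pushoff_relax, run_langevin
    from chromosteer.polymer import maxwell_boltzmann_velocities

    n = 80
    state = SystemState(build_random_walk(n, seed=9), [0, n], 500.0)
    rng = np.random.default_rng(0)
    state.vel = maxwell_boltzmann_velocities(n, 1.0, rng)
    pushoff_relax(state, ff, n_steps=2000,
                  run=RunParams(dt=0.005, friction=1.0, seed=1))
    traj = run_langevin(
        state, ff,
        RunParams(dt=0.01, n_steps=100_000, friction=0.5, seed=4,
                  snapshot_every=1000),
    )
    corr = np.zeros(9)
    count = 0
    for pos in traj.frames[40:]:
        bonds = np.diff(pos, axis=0)
        bonds /= np.linalg.norm(bonds, axis=1, keepdims=True)
        for s in range(1, 10):
            corr[s - 1] += (bonds[:-s] * bonds[s:]).sum(1).mean()
        count += 1
    corr /= count
    s_arr = np.arange(1, 10) * 0.97
    lp_fit = -1.0 / np.polyfit(s_arr, np.log(corr), 1)[0]
    # discrete Kratky-Porod theory: <cos theta> = coth(k) - 1/k per bond
    k = ff.bend_k
    lp_theory = -0.97 / np.log(1.0 / np.tanh(k) - 1.0 / k)
    assert lp_fit == pytest.approx(lp_theory, rel=0.15)
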