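import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromosteer.network import (
    LOG2_3,
    CoregNetwork,
    MIEstimate,
    clustering_coefficient,
    deduplicate_pairs,
    discretize,
    fit_null_and_threshold,
    mutual_information,
    mutual_information_matrix,
    randomize_positions,
    reshuffle_pairings,
    select_significant_pairs,
)


class TestDiscretize:
    def test_exact_tertiles(self):
        levels = discretize(np.arange(1.0, 10.0))
        assert np.array_equal(levels, [0, 0, 0, 1, 1, 1, 2, 2, 2])

    def test_constant_profile_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            levels = discretize(np.array([[1.0] * 9, list(range(9))]))
        assert (levels[0] == -1).all()
        assert (levels[1] >= 0).all()

    def test_tie_rule_matches_stable_rank_oracle(self, rng):
        for _ in range(20):
            profile = rng.integers(0, 4, size=17).astype(float)
            if len(np.unique(profile)) < 3:
                continue
            levels = discretize(profile)
            # oracle: stable sort ranks -> floor(rank*3/n)
            order = sorted(range(17), key=lambda k: (profile[k], k))
            expect = np.empty(17, dtype=int)
            for r, k in enumerate(order):
                expect[k] = (r * 3) // 17
            assert np.array_equal(levels, expect)
            assert np.array_equal(levels, discretize(profile))  # repeatable

    def test_balanced_counts(self, rng):
        profile = rng.normal(size=100)
        counts = np.bincount(discretize(profile), minlength=3)
        assert counts.max() - counts.min() <= 1


class TestMutualInformation:
    def test_identical_uniform_profiles_give_log3(self):
        lv = np.array([0, 1, 2] * 4)
        assert mutual_information(lv, lv) == pytest.approx(LOG2_3)

    def test_independent_profiles_vanish_asymptotically(self, rng):
        a = rng.integers(0, 3, size=100_000)
        b = rng.integers(0, 3, size=100_000)
        assert mutual_information(a, b) < 1e-3

    def test_hand_evaluated_tables(self):
        # oracle: direct double sum over the 3x3 joint table
        def direct(counts):
            counts = np.asarray(counts, dtype=float)
            n = counts.sum()
            total = 0.0
            for a in range(3):
                for b in range(3):
                    pab = counts[a, b] / n
                    if pab == 0:
                        continue
                    pa = counts[a, :].sum() / n
                    pb = counts[:, b].sum() / n
                    total += pab * np.log2(pab / (pa * pb))
            return total

        tables = [
            [[4, 0, 0], [0, 4, 0], [0, 0, 4]],
            [[2, 1, 1], [1, 2, 1], [1, 1, 2]],
        ]
        for table in tables:
            profile_a, profile_b = [], []
            for a in range(3):
                for b in range(3):
                    profile_a += [a] * table[a][b]
                    profile_b += [b] * table[a][b]
            got = mutual_information(np.array(profile_a), np.array(profile_b))
            assert got == pytest.approx(direct(table), abs=1e-12)
        # frozen values computed with the oracle above
        assert mutual_information(
            np.repeat([0, 1, 2], 4), np.repeat([0, 1, 2], 4)
        ) == pytest.approx(LOG2_3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([0, 1]), np.array([0, 1, 2]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=40),
           st.lists(st.integers(0, 2), min_size=1, max_size=40))
    def test_symmetry_and_range(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        mi_ab = mutual_information(a, b)
        mi_ba = mutual_information(b, a)
        assert mi_ab == pytest.approx(mi_ba, abs=1e-12)
        assert -1e-12 <= mi_ab <= LOG2_3 + 1e-12

    def test_matrix_agrees_with_pairwise(self, rng):
        levels = rng.integers(0, 3, size=(6, 40))
        mat = mutual_information_matrix(levels)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(
                    mutual_information(levels[i], levels[j]), abs=1e-10
                )
        assert np.allclose(mat, mat.T, equal_nan=True)


class TestNullFit:
    def test_single_pair_bin_selects_nothing_ordinary(self, rng):
        from scipy import stats as sps

        vals = sps.gamma.rvs(2.0, scale=0.003, size=200, random_state=1)
        seps = np.concatenate([np.full(199, 1e6), [5e6]])
        fits = fit_null_and_threshold(vals, seps, min_pairs_per_bin=50)
        # sparse far bin merged backwards; a single fit results
        assert len(fits) == 1
        assert fits[0].n_pairs_in_bin == 200

    def test_threshold_monotone_in_n_pairs(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        thresholds = []
        for n in (500, 5000):
            vals = sps.gamma.rvs(2.0, scale=0.003, size=n, random_state=2)
            seps = rng.uniform(0, 4e6, size=n)
            fits = fit_null_and_threshold(vals, seps)
            thresholds.append(fits[0].mi_threshold)
        assert thresholds[1] > thresholds[0]

    def test_degenerate_histogram_flagged(self):
        vals = np.full(100, 0.01)
        seps = np.full(100, 1e6)
        fits = fit_null_and_threshold(vals, seps)
        assert not fits[0].ok
        ests = [MIEstimate(0, k + 1, 0.01, 1e6) for k in range(100)]
        assert select_significant_pairs(ests, fits) == []

    def test_evalue_calibration_on_fitted_null(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        counts = []
        for seed in range(20):
            vals = sps.gamma.rvs(2.05, scale=0.0027, size=4000,
                                 random_state=seed)
            seps = rng.uniform(0, 4e6, size=4000)
            fits = fit_null_and_threshold(vals, seps)
            counts.append(int((vals > fits[0].mi_threshold).sum()))
        assert np.mean(counts) <= 2.0


class TestDeduplicate:
    def _net(self, selected, midpoints, merge):
        return deduplicate_pairs(selected, np.asarray(midpoints, float), merge)

    def test_identical_endpoints_keep_max_mi(self):
        sel = [MIEstimate(0, 1, 0.8, 100.0), MIEstimate(0, 1, 0.9, 100.0)]
        # distinct gene indices required; emulate near-identical loci
        sel = [MIEstimate(0, 2, 0.8, 100.0), MIEstimate(1, 3, 0.9, 100.0)]
        net = self._net(sel, [0, 1, 1000, 1001], merge=10)
        assert net.n_edges == 1
        assert net.edges[0][:2] == (1, 3)

    def test_distant_pairs_both_kept(self):
        sel = [MIEstimate(0, 1, 0.8, 1.0), MIEstimate(2, 3, 0.9, 1.0)]
        net = self._net(sel, [0, 10_000, 50_000, 90_000], merge=100)
        assert net.n_edges == 2

    def test_transitive_chain_single_survivor(self):
        # chain p0~p1~p2 under the proximity relation; brute-force
        # connected-components oracle gives one group -> max MI survives
        mids = [0, 50, 100, 10_000, 10_050, 10_100]
        sel = [
            MIEstimate(0, 3, 0.5, 1.0),
            MIEstimate(1, 4, 0.6, 1.0),
            MIEstimate(2, 5, 0.7, 1.0),
        ]
        merge = 80  # p0-p1 near, p1-p2 near, p0-p2 NOT near
        net = self._net(sel, mids, merge)
        assert net.n_edges == 1
        assert net.edges[0][2] == pytest.approx(0.7)

    def test_brute_force_grouping_oracle(self, rng):
        for trial in range(10):
            mids = rng.uniform(0, 1000, size=12)
            pairs = []
            seen = set()
            while len(pairs) < 8:
                i, j = rng.integers(0, 12, size=2)
                if i != j and (min(i, j), max(i, j)) not in seen:
                    seen.add((min(i, j), max(i, j)))
                    pairs.append(MIEstimate(int(min(i, j)), int(max(i, j)),
                                            float(rng.random()), 1.0))
            merge = 150.0

            def near(a, b):
                return abs(mids[a] - mids[b]) < merge

            # oracle: BFS components over the endpoint-matching relation
            adj = {p: set() for p in range(8)}
            for p in range(8):
                for q in range(p + 1, 8):
                    ip, jp = pairs[p].i, pairs[p].j
                    iq, jq = pairs[q].i, pairs[q].j
                    if (near(ip, iq) and near(jp, jq)) or (
                            near(ip, jq) and near(jp, iq)):
                        adj[p].add(q)
                        adj[q].add(p)
            comps = []
            todo = set(range(8))
            while todo:
                stack = [todo.pop()]
                comp = set(stack)
                while stack:
                    for nb in adj[stack.pop()]:
                        if nb not in comp:
                            comp.add(nb)
                            stack.append(nb)
                todo -= comp
                comps.append(comp)
            expect = sorted(
                max(comp, key=lambda p: pairs[p].mi) for comp in comps
            )
            expect_edges = sorted(
                (pairs[p].i, pairs[p].j, pairs[p].mi) for p in expect
            )
            net = self._net(pairs, mids, merge)
            assert sorted(net.edges) == expect_edges


class TestClustering:
    def test_triangle(self):
        net = CoregNetwork(["a", "b", "c"], np.arange(3), np.arange(3) + 1,
                           [(0, 1, 1), (0, 2, 1), (1, 2, 1)])
        st_ = clustering_coefficient(net)
        assert np.allclose(st_.clustering, 1.0)
        assert st_.mean_clustering == 1.0

    def test_star(self):
        net = CoregNetwork(["h", "l1", "l2", "l3"], np.arange(4),
                           np.arange(4) + 1,
                           [(0, 1, 1), (0, 2, 1), (0, 3, 1)])
        st_ = clustering_coefficient(net)
        assert st_.clustering[0] == 0.0
        assert np.isnan(st_.clustering[1:]).all()
        assert st_.mean_clustering == 0.0

    def test_five_node_graph_vs_triangle_enumeration(self):
        edges = [(0, 1, 1), (0, 2, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1)]
        net = CoregNetwork(list("abcde"), np.arange(5), np.arange(5) + 1,
                           edges)
        st_ = clustering_coefficient(net)
        # oracle: triple loop triangle count per node
        adj = np.zeros((5, 5), dtype=bool)
        for i, j, _ in edges:
            adj[i, j] = adj[j, i] = True
        for v in range(5):
            nb = np.nonzero(adj[v])[0]
            if len(nb) < 2:
                assert np.isnan(st_.clustering[v]) or len(nb) < 2
                continue
            tri = sum(
                adj[a, b] for ai, a in enumerate(nb) for b in nb[ai + 1:]
            )
            assert st_.clustering[v] == pytest.approx(
                2 * tri / (len(nb) * (len(nb) - 1))
            )


class TestRandomizations:
    def _clique_net(self, n_cliques=5, size=4):
        edges = []
        n = n_cliques * size
        for c in range(n_cliques):
            mem = range(c * size, (c + 1) * size)
            edges += [(a, b, 1.0) for a in mem for b in mem if a < b]
        return CoregNetwork([f"g{k}" for k in range(n)],
                            np.arange(n) * 1000, np.arange(n) * 1000 + 500,
                            edges)

    def test_reshuffle_preserves_degree_sequence(self):
        net = self._clique_net()
        for seed in range(5):
            new = reshuffle_pairings(net, fraction=1.0, seed=seed)
            assert np.array_equal(new.degree_sequence(),
                                  net.degree_sequence())
            assert new.n_edges == net.n_edges

    def test_fraction_zero_identity(self):
        net = self._clique_net()
        new = reshuffle_pairings(net, fraction=0.0, seed=1)
        assert new.edge_set() == net.edge_set()

    def test_partial_fraction_bounds_rewiring(self):
        net = self._clique_net()
        new = reshuffle_pairings(net, fraction=0.3, seed=2)
        changed = len(new.edge_set() - net.edge_set())
        assert changed >= int(np.ceil(0.3 * net.n_edges))

    def test_full_reshuffle_lowers_clustering(self):
        net = self._clique_net()
        c_native = clustering_coefficient(net).mean_clustering
        drops = []
        for seed in range(20):
            new = reshuffle_pairings(net, fraction=1.0, seed=seed)
            drops.append(clustering_coefficient(new).mean_clustering)
        assert np.median(drops) < c_native

    def test_too_few_edges_rejected(self):
        net = CoregNetwork(["a", "b"], np.arange(2), np.arange(2) + 1,
                           [(0, 1, 1.0)])
        with pytest.raises(ValueError):
            reshuffle_pairings(net, seed=0)

    def test_randomize_positions_preserves_edges_and_lengths(self):
        net = self._clique_net()
        cen = (5_000, 8_000)
        for seed in range(5):
            new = randomize_positions(net, 200_000, centromere=cen, seed=seed)
            assert new.edge_set() == net.edge_set()
            assert np.array_equal(new.ends - new.starts,
                                  net.ends - net.starts)
            inside = (new.ends > cen[0]) & (new.starts < cen[1])
            assert not inside.any()
            order = np.argsort(new.starts)
            assert (new.starts[order][1:] >= new.ends[order][:-1]).all()

    def test_randomize_positions_changes_separations(self):
        # native pairs deliberately short-range; randomization spreads them
        n = 20
        edges = [(k, k + 1, 1.0) for k in range(0, n - 1, 2)]
        net = CoregNetwork([f"g{k}" for k in range(n)],
                           np.arange(n) * 1000, np.arange(n) * 1000 + 400,
                           edges)
        from scipy.stats import ks_2samp

        def seps(network):
            mid = network.midpoints()
            return np.array([abs(mid[i] - mid[j])
                             for i, j, _ in network.edges])

        native = seps(net)
        pooled = np.concatenate([
            seps(randomize_positions(net, 500_000, seed=s)) for s in range(20)
        ])
        assert ks_2samp(native, pooled).pvalue < 0.01
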