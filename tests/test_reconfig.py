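"""AMI, reconfiguration indices, boundary pairing, participation coefficient."""

import numpy as np
import pytest
from fractions import Fraction

from scipy.stats import hypergeom
from sklearn.metrics import adjusted_mutual_info_score as sk_ami

from netreconfig.communities import PartitionSet
from netreconfig.reconfig import (
    CoassignmentCounts,
    EventBoundarySet,
    ami,
    boundary_index,
    boundary_pairs,
    coassignment,
    network_participation,
    participation,
    w2w_index,
)
from netreconfig.synthdata import gen_node_table, gen_planted_dynamics


def ami_oracle(p, q):
    """Independent AMI computation: contingency + scipy hypergeometric E[MI]."""
    p, q = np.asarray(p), np.asarray(q)
    n = len(p)
    pl, ql = np.unique(p), np.unique(q)
    cont = np.array([[(np.sum((p == a) & (q == b))) for b in ql] for a in pl])
    a, b = cont.sum(1), cont.sum(0)
    mi = 0.0
    for i in range(len(pl)):
        for j in range(len(ql)):
            nij = cont[i, j]
            if nij:
                mi += nij / n * np.log(n * nij / (a[i] * b[j]))
    emi = 0.0
    for ai in a:
        for bj in b:
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                pr = hypergeom.pmf(nij, n, ai, bj)
                emi += pr * nij / n * np.log(n * nij / (ai * bj))
    hp = -np.sum(a / n * np.log(a / n))
    hq = -np.sum(b / n * np.log(b / n))
    denom = 0.5 * (hp + hq) - emi
    return (mi - emi) / denom


class TestAmi:
    def test_identical_partitions(self):
        p = np.repeat([0, 1, 2], 4)
        assert ami(p, p) == 1.0
        assert ami(p, (p + 3) % 7 * 2) == pytest.approx(1.0)

    def test_matches_exact_hypergeometric_oracle(self):
        assert ami([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(
            ami_oracle([0, 0, 1, 1], [0, 1, 0, 1]), abs=1e-12
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.integers(0, 3, 12)
            q = rng.integers(0, 4, 12)
            assert ami(p, q) == pytest.approx(ami_oracle(p, q), abs=1e-10)
            assert ami(p, q) == pytest.approx(
                sk_ami(p, q, average_method="arithmetic"), abs=1e-10
            )

    def test_chance_level_near_zero(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            p = rng.integers(0, 5, 500)
            q = rng.integers(0, 5, 500)
            hits += abs(ami(p, q)) < 0.05
        assert hits >= 95

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.integers(0, 4, 40)
        q = rng.integers(0, 3, 40)
        assert ami(p, q) == pytest.approx(ami(q, p), abs=1e-12)
        relabel = rng.permutation(4)
        assert ami(relabel[p], q) == pytest.approx(ami(p, q), abs=1e-12)

    def test_degenerate_single_cluster_conventions(self):
        assert ami([0, 0, 0], [5, 5, 5]) == 1.0
        assert ami([0, 0, 0, 0], [0, 1, 0, 1]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ami([0, 1], [0, 1, 2])


class TestW2w:
    def test_constant_sequence_zero(self):
        P = np.tile(np.repeat([0, 1, 2], 4), (6, 1))
        assert w2w_index(P) == 0.0

    def test_alternating_independent_partitions_near_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 500)
        b = rng.integers(0, 5, 500)
        P = np.stack([a, b] * 5)
        assert abs(w2w_index(P) - 1.0) < 0.05

    def test_monotone_in_planted_switch_rate(self):
        rates = [0.0, 0.25, 0.5, 0.75, 1.0]
        idx = []
        for r in rates:
            vals = [
                w2w_index(gen_planted_dynamics(80, 40, r, 4, seed=s).partitions)
                for s in range(5)
            ]
            idx.append(np.mean(vals))
        assert (np.diff(idx) > 0).all()  # strictly increasing in switch rate

    def test_gamma_average_over_partition_set(self):
        rng = np.random.default_rng(2)
        Pa = np.stack([rng.integers(0, 3, 30) for _ in range(5)])
        Pb = np.stack([rng.integers(0, 3, 30) for _ in range(5)])
        pset = PartitionSet(by_gamma={0.95: Pa, 1.05: Pb})
        expected = 0.5 * (w2w_index(Pa) + w2w_index(Pb))
        assert w2w_index(pset) == pytest.approx(expected, abs=1e-12)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            w2w_index(np.array([[0, 1, 0]]))


class TestBoundaryPairs:
    # toy sliding grid: 40-volume windows every 2 volumes at TR 1 s
    def grid(self, n_volumes=200):
        return [(s, s + 40) for s in range(0, n_volumes - 39, 2)]

    def test_midscan_boundary_yields_one_admissible_pair(self):
        pairs = boundary_pairs(EventBoundarySet([100.0]), self.grid(), tr=1.0)
        assert len(pairs) == 1
        (i, j) = pairs[0]
        g = self.grid()
        gap = g[j][0] - g[i][1]
        assert 5.0 <= gap <= 7.0
        assert g[i][1] <= 100.0 <= g[j][0]

    def test_boundary_near_scan_start_skipped(self):
        pairs = boundary_pairs(EventBoundarySet([10.0]), self.grid(), tr=1.0)
        assert pairs == []

    def test_multiple_boundaries_enumerated(self):
        onsets = [60.0, 100.0, 140.0]
        pairs = boundary_pairs(EventBoundarySet(onsets), self.grid(), tr=1.0)
        assert len(pairs) == 3
        for i, j in pairs:
            g = self.grid()
            assert g[i][1] <= g[j][0]  # non-overlapping

    def test_infeasible_gap_tolerance_drops_boundaries(self):
        # a coarse grid stepping 20 volumes cannot bracket every boundary
        coarse = [(s, s + 40) for s in range(0, 161, 20)]
        onsets = [60.0, 70.0, 100.0, 130.0]
        pairs = boundary_pairs(
            EventBoundarySet(onsets, gap_range_s=(5.0, 7.0)), coarse, tr=1.0
        )
        assert len(pairs) < len(onsets)


class TestBoundaryIndex:
    def test_identical_pairs_zero(self):
        P = np.tile(np.repeat([0, 1], 10), (8, 1))
        assert boundary_index(P, [(0, 4), (2, 6)]) == 0.0

    def test_planted_boundary_changes_dominate(self):
        rng = np.random.default_rng(0)
        # partitions constant within segments, switching only at two boundaries
        seg = [rng.integers(0, 4, 200) for _ in range(3)]
        P = np.stack([seg[0]] * 4 + [seg[1]] * 4 + [seg[2]] * 4)
        b_idx = boundary_index(P, [(3, 4), (7, 8)])
        w_idx = w2w_index(P)
        assert b_idx > 2 * w_idx
        control = boundary_index(P, [(0, 2), (4, 6)])
        assert control < 0.05

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            boundary_index(np.zeros((3, 5), dtype=int), [])


class TestCoassignment:
    def test_single_window_all_together(self):
        c = coassignment(np.zeros((1, 4), dtype=int))
        off = ~np.eye(4, dtype=bool)
        assert (c.k[off] == 1).all()
        assert (np.diag(c.k) == 0).all()

    def test_sum_of_window_indicators(self):
        P = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        expect = np.zeros((4, 4), dtype=int)
        for p in P:
            expect += (p[:, None] == p[None, :]).astype(int)
        np.fill_diagonal(expect, 0)
        assert np.array_equal(coassignment(P).k, expect)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        P = rng.integers(0, 3, (6, 10))
        k = coassignment(P).k
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                assert k[i, j] == sum(P[w, i] == P[w, j] for w in range(6))


class TestParticipation:
    def atlas(self, n_nodes, n_networks, seed=0):
        return gen_node_table(n_nodes, n_networks, seed=seed)

    def test_within_network_only_gives_zero(self):
        atlas = self.atlas(10, 2, seed=1)
        comm = atlas["atlas_community"].to_numpy()
        k = np.where(comm[:, None] == comm[None, :], 5, 0)
        np.fill_diagonal(k, 0)
        P = participation(CoassignmentCounts(k=k, n_windows=5), atlas)
        assert np.allclose(P, 0.0)

    def test_equal_spread_closed_form(self):
        atlas = self.atlas(20, 10, seed=2)
        comm = atlas["atlas_community"].to_numpy()
        # co-assign each node equally with one node of every network
        k = np.zeros((20, 20), dtype=int)
        for i in range(20):
            for m in range(10):
                j = np.flatnonzero(comm == m)[0]
                if j != i:
                    k[i, j] = 4
        k = np.maximum(k, k.T)
        P = participation(CoassignmentCounts(k=k, n_windows=8), atlas)
        # nodes whose co-assignments spread equally over all 10 networks hit 0.9
        kim = np.array([[k[i, comm == m].sum() for m in range(10)] for i in range(20)])
        spread = [i for i in range(20) if np.ptp(kim[i]) == 0 and kim[i, 0] > 0]
        assert len(spread) > 0
        assert np.allclose(P[spread], 0.9, atol=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        atlas = self.atlas(15, 4, seed=3)
        comm = atlas["atlas_community"].to_numpy()
        k = rng.integers(0, 6, (15, 15))
        k = np.triu(k, 1)
        k = k + k.T
        P = participation(CoassignmentCounts(k=k, n_windows=10), atlas)
        for i in range(15):
            ki = k[i].sum()
            expect = 1.0 - sum(
                (k[i, comm == m].sum() / ki) ** 2 for m in range(4)
            ) if ki else 0.0
            assert P[i] == pytest.approx(expect, abs=1e-12)
        M = 4
        assert (P <= 1 - 1 / M + 1e-12).all()
        assert (P >= 0).all()


class TestNetworkParticipation:
    def test_constant_and_localized_values(self):
        atlas = gen_node_table(12, 3, seed=5)
        P = np.full(12, 0.4)
        means = network_participation(P, atlas)
        assert np.allclose(means.to_numpy(), 0.4)
        mask = (atlas["network"] == means.index[0]).to_numpy()
        P2 = np.where(mask, 0.9, 0.0)
        means2 = network_participation(P2, atlas)
        assert means2[means.index[0]] == pytest.approx(0.9)
        assert np.allclose(means2.drop(means.index[0]).to_numpy(), 0.0)

    def test_matches_grouped_mean_oracle(self, rng):
        atlas = gen_node_table(30, 5, seed=6)
        P = rng.random(30)
        means = network_participation(P, atlas)
        for net in means.index:
            mask = (atlas["network"] == net).to_numpy()
            assert means[net] == pytest.approx(P[mask].mean(), abs=1e-12)
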