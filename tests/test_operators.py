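import math

import numpy as np
import pytest

from conftest import random_timetree
from constclock.fixtures import make_fixture, three_taxon_tree
from constclock.hky import HKYModel, pruning_log_likelihood, simulate_alignment
from constclock.operators import (BigPulleyOperator, OperatorConfig,
                                  ProposalResult, exchange,
                                  propose_big_pulley, propose_internal_node,
                                  propose_simple_distance,
                                  propose_small_pulley)
from constclock.timetree import TimeTree, TreeError
from helpers import (big_pulley_fd_error, internal_node_fd_error,
                     simple_distance_fd_error, small_pulley_fd_jacobian)


def worked_example_tree():
    # t_P = 10, t_X = 1, tips at 0; r_X = 0.04, r_L = 0.1, r_R = 0.2
    return three_taxon_tree(d_A=0.1, d_B=0.2, d_C=0.4, d_D=0.36,
                            t_D=1.0, t_E=10.0)


class TestInternalNode:
    def test_worked_example(self):
        tree = worked_example_tree()
        res = propose_internal_node(tree, 3, OperatorConfig(), None, a=1.0)
        assert res.valid
        assert res.tree.times[3] == pytest.approx(2.0)
        assert res.tree.rates[3] == pytest.approx(0.045)   # r_X'
        assert res.tree.rates[0] == pytest.approx(0.05)    # r_L'
        assert res.tree.rates[1] == pytest.approx(0.10)    # r_R'
        assert math.exp(res.log_green) == pytest.approx((9 / 8) * 0.5 * 0.5)

    def test_zero_displacement_is_identity(self):
        tree = worked_example_tree()
        res = propose_internal_node(tree, 3, OperatorConfig(), None, a=0.0)
        assert res.log_green == pytest.approx(0.0)
        assert np.allclose(res.tree.times, tree.times)
        assert np.allclose(res.tree.rates[:4], tree.rates[:4])

    def test_out_of_bounds_rejected(self):
        tree = worked_example_tree()
        assert not propose_internal_node(tree, 3, OperatorConfig(), None, a=-2.0).valid
        assert not propose_internal_node(tree, 3, OperatorConfig(), None, a=9.5).valid

    def test_root_or_tip_raises(self):
        tree = worked_example_tree()
        with pytest.raises(TreeError):
            propose_internal_node(tree, tree.root, OperatorConfig(), None, a=0.1)
        with pytest.raises(TreeError):
            propose_internal_node(tree, 0, OperatorConfig(), None, a=0.1)

    def test_distance_conservation_sweep(self, rng):
        tree = worked_example_tree()
        d0 = tree.branch_distances()
        for _ in range(500):
            res = propose_internal_node(tree, 3, OperatorConfig(w=2.0), rng)
            if res.valid:
                d1 = res.tree.branch_distances()
                assert np.nanmax(np.abs(d1 - d0)) <= 1e-12
                tree = res.tree

    def test_jacobian_matches_finite_difference(self, rng):
        errs = []
        while len(errs) < 100:
            tD = rng.uniform(0.5, 5.0)
            tE = tD + rng.uniform(0.5, 5.0)
            tree = three_taxon_tree(*rng.uniform(0.05, 1.0, 4), tD, tE)
            e = internal_node_fd_error(tree, 3, rng.uniform(-0.5, 0.5) * tD)
            if e is not None:
                errs.append(e)
        assert max(errs) <= 1e-6


class TestSimpleDistance:
    def test_worked_example(self):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        res = propose_simple_distance(tree, OperatorConfig(), None, a=2.0)
        assert math.exp(res.log_green) == pytest.approx((9 / 11) * (10 / 12))

    def test_identity_and_rejection(self):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        assert propose_simple_distance(tree, OperatorConfig(), None, a=0.0).log_green == 0.0
        assert not propose_simple_distance(tree, OperatorConfig(), None, a=-9.5).valid

    def test_distance_conservation_sweep(self, rng):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        d0 = tree.branch_distances()
        kept = 0
        for _ in range(1000):
            res = propose_simple_distance(tree, OperatorConfig(w=3.0), rng)
            if res.valid:
                assert np.nanmax(np.abs(res.tree.branch_distances() - d0)) <= 1e-12
                tree = res.tree
                kept += 1
        assert kept > 100

    def test_jacobian_matches_finite_difference(self, rng):
        errs = []
        while len(errs) < 100:
            tD = rng.uniform(0.5, 5.0)
            tE = tD + rng.uniform(0.5, 5.0)
            tree = three_taxon_tree(*rng.uniform(0.05, 1.0, 4), tD, tE)
            e = simple_distance_fd_error(tree, rng.uniform(-1.0, 2.0))
            if e is not None:
                errs.append(e)
        assert max(errs) <= 1e-6


class TestSmallPulley:
    def test_green_ratio_exactly_one(self, rng):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        for _ in range(50):
            res = propose_small_pulley(tree, OperatorConfig(v=0.2), rng)
            if res.valid:
                assert res.log_green == 0.0
                tree = res.tree

    def test_total_distance_conserved(self, rng):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        L, R = tree.children[tree.root]
        D = tree.branch_distance(L) + tree.branch_distance(R)
        for _ in range(500):
            res = propose_small_pulley(tree, OperatorConfig(v=0.2), rng)
            if res.valid:
                tree = res.tree
                got = tree.branch_distance(L) + tree.branch_distance(R)
                assert got == pytest.approx(D, abs=1e-12)

    def test_rate_map_jacobian_is_identity(self, rng):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        J = small_pulley_fd_jacobian(tree, b=0.05)
        assert np.allclose(J, np.eye(2), atol=1e-7)

    def test_boundary_rejection(self):
        tree = three_taxon_tree(0.1, 0.2, 0.4, 0.27, 1.0, 10.0)
        L, _ = tree.children[tree.root]
        dL = tree.branch_distance(L)
        assert not propose_small_pulley(tree, OperatorConfig(), None, b=-dL).valid
        eps = 1e-6
        assert propose_small_pulley(tree, OperatorConfig(), None, b=-dL + eps).valid


class TestExchange:
    def _four_taxon_tree(self, dS, dM, dN, dC):
        # root X with children C (internal: S, M) and tip N; S, M are a cherry
        taxa = ["S1", "S2", "M", "N"]
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        children = [(), (), (), (), (0, 1), (4, 2), (5, 3)]
        times = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 2.0, 4.0])
        rates = np.array([0.05 / 1.0, 0.05 / 1.0, dM / 2.0, dN / 4.0,
                          dS / 1.0, dC / 2.0, np.nan])
        t = TimeTree(taxa, parent, children, times, rates)
        t.validate()
        return t

    def test_worked_distance_update(self):
        t = self._four_taxon_tree(dS=0.1, dM=0.5, dN=0.2, dC=0.1)
        D0 = t.pairwise_distances()
        parent, children, dist, valid = exchange(t, M=2, N=3, b=0.05)
        assert valid
        assert dist[5] == pytest.approx(0.15)   # d_C'
        assert dist[2] == pytest.approx(0.35)   # d_M'
        assert dist[3] == pytest.approx(0.30)   # d_N'
        assert dist[4] == pytest.approx(0.10)   # d_S'
        # rebuild a tree with the same times and check path conservation
        # among the cherry (S), M and N
        new = t.copy()
        new.parent, new.children = parent, children
        for node, d in dist.items():
            p = parent[node]
            new.rates[node] = d / (new.times[p] - new.times[node])
        D1 = new.pairwise_distances()
        assert np.allclose(D0, D1, atol=1e-12)

    def test_boundary_validity(self):
        t = self._four_taxon_tree(dS=0.1, dM=0.5, dN=0.2, dC=0.1)
        *_, valid = exchange(t, M=2, N=3, b=-0.1)      # d_C' = 0
        assert not valid
        *_, valid = exchange(t, M=2, N=3, b=-0.1 + 1e-9)
        assert valid

    def test_mirror_restores_original(self):
        t = self._four_taxon_tree(dS=0.1, dM=0.5, dN=0.2, dC=0.1)
        parent, children, dist, _ = exchange(t, M=2, N=3, b=0.05)
        fwd = t.copy()
        fwd.parent, fwd.children = parent, children
        for node, d in dist.items():
            fwd.rates[node] = d / (fwd.times[parent[node]] - fwd.times[node])
        p2, c2, dist2, _ = exchange(fwd, M=3, N=2, b=-0.05)
        assert np.array_equal(p2, t.parent)
        for node, d in dist2.items():
            assert d == pytest.approx(t.branch_distance(node), abs=1e-12)

    def test_bad_configuration_raises(self):
        t = self._four_taxon_tree(dS=0.1, dM=0.5, dN=0.2, dC=0.1)
        with pytest.raises(TreeError):
            exchange(t, M=0, N=3, b=0.01)  # M not a child of C


class TestBigPulley:
    def test_pairwise_distances_conserved(self, rng):
        _, tree = make_fixture("big_pulley")
        D0 = tree.pairwise_distances()
        accepted = 0
        for _ in range(500):
            res = propose_big_pulley(tree, OperatorConfig(w=1.0, v=0.05), rng)
            if res.valid:
                res.tree.validate()
                assert np.max(np.abs(res.tree.pairwise_distances() - D0)) <= 1e-10
                tree = res.tree
                accepted += 1
        assert accepted > 100

    def test_three_taxon_topology_ratio_is_one(self, rng):
        # asymmetric <-> asymmetric with contemporaneous tips: both swaps
        # are always admissible, so mu = 0.5 / 0.5 = 1 and the Green ratio
        # is the bare Jacobian
        _, tree = make_fixture("big_pulley")
        res = propose_big_pulley(tree, OperatorConfig(), None,
                                 a=0.5, a2=-0.5, b=0.02, choice=0.3)
        assert res.valid
        tX, tC = tree.times[4], tree.times[3]
        tXn, tCn = tX + 0.5, tC - 0.5
        expect = ((tX - tC) / (tXn - tCn)) * (tC / tCn) * (tC / tXn) * (tX / tCn)
        assert math.exp(res.log_green) == pytest.approx(expect, rel=1e-12)

    def test_symmetric_shape_topology_ratio_is_one(self, rng):
        # 4-taxon symmetric root: forward and reverse picks are both blind
        # 0.25 choices
        tree = random_timetree(4, rng)
        # force the symmetric shape: ((a,b),(c,d)) style trees only
        while any(tree.is_tip(c) for c in tree.children[tree.root]):
            tree = random_timetree(4, rng)
        found = 0
        for _ in range(300):
            res = propose_big_pulley(tree, OperatorConfig(w=0.3, v=0.02), rng)
            if res.valid:
                found += 1
                # mu == 1 iff the proposed tree is symmetric too; verify via
                # the involution: reapplying the reverse displacement from
                # the proposal restores the original Green ratio sign
                assert math.isfinite(res.log_green)
        assert found > 10

    def test_heterochronous_forced_move_has_half_ratio(self):
        # asymmetric tree with an older grandchild: proposing the internal
        # node below it forces the single admissible swap (prob 1) whose
        # reverse is a 0.5 choice -> mu = 0.5
        taxa = ["G1", "G2", "Y"]
        parent = np.array([3, 3, 4, 4, -1])
        children = [(), (), (), (0, 1), (3, 2)]
        times = np.array([2.0, 0.0, 0.0, 3.0, 6.0])  # G1 is an old tip
        rates = np.array([1.0, 0.1, 0.1, 0.1, np.nan])
        tree = TimeTree(taxa, parent, children, times, rates)
        tree.validate()
        # a2 drops t_C from 3.0 to 1.0 < t_G1 = 2.0: Exchange(G1, Y) forced
        res = propose_big_pulley(tree, OperatorConfig(), None,
                                 a=0.0, a2=-2.0, b=0.05, choice=0.9)
        assert res.valid
        assert res.tree.parent[0] == 4          # G1 hoisted to the root
        tX, tC, tXn, tCn = 6.0, 3.0, 6.0, 1.0
        jac = ((tX - tC) / (tXn - tCn)) * ((tC - 0.0) / (tCn - 0.0)) \
            * ((tC - 2.0) / (tXn - 2.0)) * ((tX - 0.0) / (tCn - 0.0))
        assert math.exp(res.log_green) == pytest.approx(0.5 * jac, rel=1e-12)

    def test_forward_reverse_ratio_product_is_one(self, rng):
        # mu(g -> g') * mu(g' -> g) = 1 along a sampled move chain
        _, tree = make_fixture("big_pulley")
        for _ in range(100):
            a, a2, b = rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5), rng.uniform(-0.05, 0.05)
            ch = rng.random()
            res = propose_big_pulley(tree, OperatorConfig(), None,
                                     a=a, a2=a2, b=b, choice=ch)
            if not res.valid:
                continue
            # the reverse displacement restores the original state
            back = None
            for ch2 in (0.3, 0.8):
                cand = propose_big_pulley(res.tree, OperatorConfig(), None,
                                          a=-a, a2=-a2, b=-b, choice=ch2)
                if cand.valid and np.array_equal(cand.tree.parent, tree.parent):
                    back = cand
                    break
            assert back is not None
            assert np.allclose(back.tree.times, tree.times, atol=1e-12)
            assert np.allclose(back.tree.rates[:-1], tree.rates[:-1], atol=1e-10)
            assert back.log_green + res.log_green == pytest.approx(0.0, abs=1e-9)
            tree = res.tree

    def test_jacobian_matches_finite_difference(self, rng):
        errs = []
        while len(errs) < 100:
            tD = rng.uniform(1.0, 5.0)
            tE = tD + rng.uniform(1.0, 5.0)
            tree = three_taxon_tree(*rng.uniform(0.1, 1.0, 4), tD, tE)
            e = big_pulley_fd_error(tree, rng.uniform(-0.5, 0.5),
                                    rng.uniform(-0.5, 0.5),
                                    rng.uniform(-0.05, 0.05), rng.random())
            if e is not None:
                errs.append(e)
        assert max(errs) <= 1e-6

    def test_cherry_only_root_disabled(self, rng):
        from constclock.timetree import TimeTree
        t = TimeTree(["A", "B"], np.array([2, 2, -1]), [(), (), (0, 1)],
                     np.array([0.0, 0.0, 1.0]), np.array([0.1, 0.1, np.nan]))
        assert not propose_big_pulley(t, OperatorConfig(), rng).valid


class TestLikelihoodInvariance:
    @pytest.mark.parametrize("op_name", ["internal", "simple_distance",
                                         "small_pulley", "big_pulley"])
    def test_accepted_proposals_keep_likelihood(self, op_name, rng):
        model = HKYModel(2.4751, (0.25, 0.25, 0.25, 0.25))
        _, tree = make_fixture("big_pulley")
        aln = simulate_alignment(tree, model, 200, rng)
        ll0 = pruning_log_likelihood(tree, aln, model)
        cfg = OperatorConfig(w=0.8, v=0.04)
        checked = 0
        while checked < 20:
            if op_name == "internal":
                node = next(v for v in range(3, 5) if v != tree.root)
                res = propose_internal_node(tree, node, cfg, rng)
            elif op_name == "simple_distance":
                res = propose_simple_distance(tree, cfg, rng)
            elif op_name == "small_pulley":
                res = propose_small_pulley(tree, cfg, rng)
            else:
                res = propose_big_pulley(tree, cfg, rng)
            if res.valid:
                ll = pruning_log_likelihood(res.tree, aln, model)
                assert ll == pytest.approx(ll0, abs=1e-10)
                tree = res.tree
                checked += 1
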