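import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from conftest import random_timetree
from constclock.fixtures import three_taxon_tree
from constclock.hky import (Alignment, HKYModel, pruning_log_likelihood,
                            read_fasta, simulate_alignment, transition_matrix,
                            write_fasta)
from constclock.operators import OperatorConfig, propose_big_pulley


@pytest.fixture(scope="module")
def model():
    return HKYModel(2.0, (0.3, 0.2, 0.3, 0.2))


class TestTransitionMatrix:
    def test_identity_at_zero(self, model):
        assert np.allclose(transition_matrix(model, 0.0), np.eye(4), atol=1e-12)

    def test_rows_sum_to_one_and_limit_is_pi(self, model):
        for d in (0.01, 0.5, 3.0):
            P = transition_matrix(model, d)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(transition_matrix(model, 200.0),
                           np.tile(model.pi, (4, 1)), atol=1e-10)

    def test_jukes_cantor_closed_form(self):
        jc = HKYModel(1.0)
        for d in (0.05, 0.3, 1.2):
            P = transition_matrix(jc, d)
            diag = 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
            off = 0.25 - 0.25 * math.exp(-4.0 * d / 3.0)
            assert np.allclose(np.diag(P), diag, atol=1e-12)
            assert P[0, 1] == pytest.approx(off, abs=1e-12)

    @pytest.mark.parametrize("kappa,pi", [(2.0, (0.3, 0.2, 0.3, 0.2)),
                                          (8.0, (0.1, 0.4, 0.15, 0.35)),
                                          (0.5, (0.25, 0.25, 0.25, 0.25))])
    def test_matches_scipy_expm(self, kappa, pi):
        m = HKYModel(kappa, pi)
        for d in (0.0, 0.2, 1.0, 5.0):
            assert np.allclose(transition_matrix(m, d), expm(m.Q * d), atol=1e-10)

    def test_detailed_balance_and_normalization(self, model):
        Q = model.Q
        pi = model.pi
        flow = pi[:, None] * Q
        assert np.allclose(flow, flow.T, atol=1e-12)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_negative_distance_rejected(self, model):
        with pytest.raises(ValueError):
            transition_matrix(model, -0.1)


class TestPruning:
    def test_zero_distance_two_identical_taxa(self, model):
        # one site, both 'A', no substitutions: likelihood is pi_A
        from constclock.timetree import TimeTree
        tree = TimeTree(["A", "B"], np.array([2, 2, -1]), [(), (), (0, 1)],
                        np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, np.nan]))
        aln = Alignment(["A", "B"], ["A", "A"])
        ll = pruning_log_likelihood(tree, aln, model, distances=[0.0, 0.0, np.nan])
        assert ll == pytest.approx(math.log(model.pi[0]), abs=1e-12)

    def test_matches_exhaustive_ancestral_sum(self, model, rng):
        tree = three_taxon_tree(*rng.uniform(0.05, 0.8, 4), 1.0, 10.0)
        aln = Alignment(["A", "B", "C"], ["AC", "GT", "TA"])
        ll = pruning_log_likelihood(tree, aln, model)
        d = tree.branch_distances()
        P = {i: transition_matrix(model, d[i]) for i in range(4)}
        tot = 0.0
        for site in range(2):
            obs = ["ACGT".index(aln.seqs[k][site]) for k in range(3)]
            s = 0.0
            for xD in range(4):
                for xE in range(4):
                    s += (model.pi[xE] * P[3][xE, xD] * P[0][xD, obs[0]]
                          * P[1][xD, obs[1]] * P[2][xE, obs[2]])
            tot += math.log(s)
        assert ll == pytest.approx(tot, abs=1e-10)

    def test_rerooting_invariance(self, model, rng):
        # a Big Pulley move re-hangs the root without changing the unrooted
        # tree; the reversible-model likelihood must be identical
        tree = three_taxon_tree(0.3, 0.25, 0.2, 0.15, 2.0, 5.0)
        aln = simulate_alignment(tree, model, 300, rng)
        ll0 = pruning_log_likelihood(tree, aln, model)
        moved = 0
        while moved < 5:
            res = propose_big_pulley(tree, OperatorConfig(w=0.5, v=0.05), rng)
            if res.valid:
                assert pruning_log_likelihood(res.tree, aln, model) == \
                    pytest.approx(ll0, abs=1e-10)
                moved += 1

    def test_ambiguity_and_gap_partials(self, model):
        tree = three_taxon_tree(0.1, 0.1, 0.1, 0.1, 1.0, 2.0)
        full = pruning_log_likelihood(tree, Alignment(["A", "B", "C"], ["A", "C", "G"]), model)
        # N and '-' are full uncertainty: summing over the 4 resolutions of
        # taxon C must reproduce the gapped likelihood
        gap = pruning_log_likelihood(tree, Alignment(["A", "B", "C"], ["A", "C", "-"]), model)
        parts = [math.exp(pruning_log_likelihood(
            tree, Alignment(["A", "B", "C"], ["A", "C", b]), model))
            for b in "ACGT"]
        assert gap == pytest.approx(math.log(sum(parts)), abs=1e-10)

    def test_taxa_mismatch_raises(self, model):
        tree = three_taxon_tree(0.1, 0.1, 0.1, 0.1, 1.0, 2.0)
        with pytest.raises(ValueError, match="mismatch"):
            pruning_log_likelihood(tree, Alignment(["A", "B", "X"], ["A", "C", "G"]), model)


class TestSimulate:
    def test_zero_distance_copies_root(self, model, rng):
        tree = three_taxon_tree(0.1, 0.1, 0.1, 0.1, 1.0, 2.0)
        aln = simulate_alignment(tree, model, 50, rng,
                                 distances=np.zeros(tree.n_nodes))
        assert aln.seqs[0] == aln.seqs[1] == aln.seqs[2]

    def test_long_branch_reaches_stationarity(self, model, rng):
        tree = three_taxon_tree(0.1, 0.1, 50.0, 0.1, 1.0, 10.0)
        n = 10_000
        aln = simulate_alignment(tree, model, n, rng)
        for b, p in zip("ACGT", model.pi):
            freq = aln.seqs[2].count(b) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3.5 * se

    def test_ml_distance_recovery_two_taxa(self, model, rng):
        from constclock.timetree import TimeTree
        d_true = 0.2
        tree = TimeTree(["A", "B"], np.array([2, 2, -1]), [(), (), (0, 1)],
                        np.array([0.0, 0.0, 1.0]),
                        np.array([d_true / 2, d_true / 2, np.nan]))
        n = 50_000
        aln = simulate_alignment(tree, model, n, rng)

        def nll(d):
            return -pruning_log_likelihood(tree, aln, model,
                                           distances=[d / 2, d / 2, np.nan])
        opt = minimize_scalar(nll, bounds=(0.01, 1.0), method="bounded")
        # asymptotic SE of the MLE via the curvature at the optimum
        h = 1e-3
        curv = (nll(opt.x + h) - 2 * nll(opt.x) + nll(opt.x - h)) / h ** 2
        se = 1.0 / math.sqrt(curv)
        assert abs(opt.x - d_true) < 3 * se

    def test_seed_reproducibility(self, model):
        tree = three_taxon_tree(0.2, 0.3, 0.4, 0.2, 1.0, 3.0)
        a1 = simulate_alignment(tree, model, 100, 42)
        a2 = simulate_alignment(tree, model, 100, 42)
        assert a1.seqs == a2.seqs


def test_fasta_round_trip(tmp_path):
    aln = Alignment(["A", "B"], ["ACGT", "A-NT"])
    path = tmp_path / "x.fasta"
    with open(path, "w") as fh:
        write_fasta(aln, fh)
    with open(path) as fh:
        back = read_fasta(fh)
    assert back.taxa == aln.taxa and back.seqs == aln.seqs
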