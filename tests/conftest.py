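import numpy as np
import pytest

from constclock.calibrate import simulate_yule_tree
from constclock.priors import LogNormalPrior
from constclock.timetree import TimeTree, UnrootedTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


def random_timetree(n_taxa: int, rng, rate_prior=LogNormalPrior(-1.0, 0.5),
                    lam: float = 1.0) -> TimeTree:
    """Random Yule topology/times with iid lognormal branch rates."""
    tree = simulate_yule_tree(n_taxa, lam, rng)
    rates = np.exp(rng.normal(rate_prior.m, rate_prior.s, tree.n_nodes))
    rates[tree.root] = np.nan
    tree.rates = rates
    tree.validate()
    return tree


def unrooted_from_timetree(tree: TimeTree) -> UnrootedTree:
    """Suppress the root: branches keep their genetic distances; the two
    root-adjacent branches merge into one edge."""
    d = tree.branch_distances()
    root = tree.root
    c1, c2 = tree.children[root]
    edges = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0 or v in (c1, c2):
            continue
        edges.append((int(p), v, float(d[v])))
    edges.append((c1, c2, float(d[c1] + d[c2])))
    # vertex renumber: drop the root id by mapping it away (it has no edges)
    used = sorted({x for u, v, _ in edges for x in (u, v)})
    remap = {x: i for i, x in enumerate(used)}
    edges = [(remap[u], remap[v], w) for u, v, w in edges]
    ut = UnrootedTree(list(tree.taxa), len(used), edges)
    ut.validate()
    return ut
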