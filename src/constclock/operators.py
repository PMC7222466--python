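"""Constant-genetic-distance proposal kernels and their Green ratios.

All four operators move divergence times and/or branch rates while keeping
the implied genetic distances ``d_i = r_i * dt_i`` constant, so that the
phylogenetic likelihood is unchanged for a fixed substitution model (exactly,
for any model, under the internal-node and Simple Distance moves; for
time-reversible models under the pulleys, which relocate the root on the
underlying unrooted tree).

Green ratios (the Hastings ratio extended with the Jacobian determinant of
the deterministic dimension-matching map):

* internal node:   prod over the three rescaled branches of dt_old / dt_new
* Simple Distance: prod over the two root branches of dt_old / dt_new
* Small Pulley:    1 (times fixed; the rate map has unit Jacobian)
* Big Pulley:      mu * (t_X - t_C)/(t_X' - t_C') * (t_C - t_S)/(t_C' - t_S)
                   * (t_C - t_M)/(t_X' - t_M) * (t_X - t_N)/(t_C' - t_N)

where ``mu`` is the ratio of reverse to forward topology-selection
probability.  The first Big Pulley factor is ``t_X - t_C`` (the *current*
root-child span): this is what direct differentiation of the proposal map
gives, it is the unique choice satisfying the involution identity
``|J(forward)| * |J(reverse)| = 1`` for the self-inverse Exchange map, and
it is enforced by the finite-difference Jacobian tests.

Out-of-bounds proposals are returned as invalid (counted as rejections, not
resampled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .timetree import TimeTree, TreeError

__all__ = [
    "OperatorConfig", "ProposalResult",
    "propose_internal_node", "propose_simple_distance",
    "propose_small_pulley", "propose_big_pulley",
    "exchange", "topology_proposal_ratio",
    "InternalNodeOperator", "SimpleDistanceOperator",
    "SmallPulleyOperator", "BigPulleyOperator",
    "RateWalkOperator", "RootAgeScaleOperator",
    "NodeTimeUniformOperator", "AllTimesScaleOperator",
]


@dataclass
class OperatorConfig:
    """Tuning knobs for the displacement kernels.

    ``w``: half-width of the uniform time window (time units).  ``v``:
    half-width of the uniform distance window (substitutions/site).  When
    ``None``, 10% of the current tree height / of the relevant distance sum
    is used.  ``kernel`` is a hook for alternative displacement kernels;
    only the uniform kernel is provided.
    """

    w: float | None = None
    v: float | None = None
    kernel: str = "uniform"

    def draw_time(self, rng, tree_height: float) -> float:
        w = self.w if self.w is not None else 0.1 * tree_height
        return float(rng.uniform(-w, w))

    def draw_distance(self, rng, dist_sum: float) -> float:
        v = self.v if self.v is not None else 0.1 * dist_sum
        return float(rng.uniform(-v, v))


@dataclass
class ProposalResult:
    """Outcome of one proposal: the proposed tree, the log Green ratio, and
    whether the proposal is in-bounds.  ``changed`` lists the nodes whose
    branch (above the node) was touched; ``distances_changed`` is False for
    all four constant-distance kernels."""

    tree: TimeTree | None
    log_green: float
    valid: bool
    changed: tuple = ()
    distances_changed: bool = False

    @classmethod
    def reject(cls) -> "ProposalResult":
        return cls(None, -math.inf, False)


def _share_structure(tree: TimeTree, times: np.ndarray, rates: np.ndarray) -> TimeTree:
    # topology untouched: share taxa/parent/children, new times/rates
    new = TimeTree.__new__(TimeTree)
    new.taxa = tree.taxa
    new.parent = tree.parent
    new.children = tree.children
    new.times = times
    new.rates = rates
    return new


# ---------------------------------------------------------------------------
# internal node
# ---------------------------------------------------------------------------

def propose_internal_node(tree: TimeTree, node: int, cfg: OperatorConfig,
                          rng, a: float | None = None) -> ProposalResult:
    """Shift an internal node's age by ``a ~ U[-w, w]`` and rescale the three
    adjacent branch rates so their genetic distances are unchanged."""
    p = int(tree.parent[node])
    if p < 0 or tree.is_tip(node):
        raise TreeError("internal-node move needs an internal non-root node")
    L, R = tree.children[node]
    tX = float(tree.times[node]); tP = float(tree.times[p])
    tL = float(tree.times[L]); tR = float(tree.times[R])
    if a is None:
        a = cfg.draw_time(rng, tree.tree_height())
    tXn = tX + a
    if not (max(tL, tR) < tXn < tP):
        return ProposalResult.reject()
    times = tree.times.copy(); rates = tree.rates.copy()
    times[node] = tXn
    rates[node] = rates[node] * (tP - tX) / (tP - tXn)
    rates[L] = rates[L] * (tX - tL) / (tXn - tL)
    rates[R] = rates[R] * (tX - tR) / (tXn - tR)
    log_green = (math.log((tP - tX) / (tP - tXn))
                 + math.log((tX - tL) / (tXn - tL))
                 + math.log((tX - tR) / (tXn - tR)))
    return ProposalResult(_share_structure(tree, times, rates), log_green,
                          True, changed=(node, L, R))


# ---------------------------------------------------------------------------
# root operators
# ---------------------------------------------------------------------------

def propose_simple_distance(tree: TimeTree, cfg: OperatorConfig, rng,
                            a: float | None = None) -> ProposalResult:
    """Shift the root age and rescale the two root-adjacent rates so their
    genetic distances are unchanged."""
    X = tree.root
    L, R = tree.children[X]
    tX = float(tree.times[X]); tL = float(tree.times[L]); tR = float(tree.times[R])
    if a is None:
        a = cfg.draw_time(rng, tree.tree_height())
    tXn = tX + a
    if not tXn > max(tL, tR):
        return ProposalResult.reject()
    times = tree.times.copy(); rates = tree.rates.copy()
    times[X] = tXn
    rates[L] = rates[L] * (tX - tL) / (tXn - tL)
    rates[R] = rates[R] * (tX - tR) / (tXn - tR)
    log_green = (math.log((tX - tL) / (tXn - tL))
                 + math.log((tX - tR) / (tXn - tR)))
    return ProposalResult(_share_structure(tree, times, rates), log_green,
                          True, changed=(L, R))


def propose_small_pulley(tree: TimeTree, cfg: OperatorConfig, rng,
                         b: float | None = None) -> ProposalResult:
    """Slide genetic distance between the two root branches: ``d_L' = d_L + b``
    with ``D = d_L + d_R`` conserved; times unchanged; Green ratio exactly 1."""
    X = tree.root
    L, R = tree.children[X]
    tX = float(tree.times[X]); tL = float(tree.times[L]); tR = float(tree.times[R])
    dL = float(tree.rates[L]) * (tX - tL)
    dR = float(tree.rates[R]) * (tX - tR)
    D = dL + dR
    if b is None:
        b = cfg.draw_distance(rng, D)
    dLn = dL + b
    if not (0.0 < dLn < D):
        return ProposalResult.reject()
    rates = tree.rates.copy()
    rates[L] = dLn / (tX - tL)
    rates[R] = (D - dLn) / (tX - tR)
    return ProposalResult(_share_structure(tree, tree.times.copy(), rates),
                          0.0, True, changed=(L, R))


# ---------------------------------------------------------------------------
# Big Pulley
# ---------------------------------------------------------------------------

def exchange(tree: TimeTree, M: int, N: int, b: float):
    """Prune-regraft swap of ``M`` (grandchild of the root via ``C``) and
    ``N`` (the root's other child), with distances adjusted to keep the
    pairwise distances among S, M, N unchanged:

        d_C' = d_C + b,  d_N' = d_N + d_C,  d_M' = d_M - d_C',  d_S' = d_S.

    Returns ``(parent, children, dist, valid)`` where ``dist`` maps node ->
    new branch distance for the four affected branches; times are untouched.
    Raises :class:`TreeError` if the nodes are not in the required
    configuration.
    """
    X = tree.root
    if int(tree.parent[N]) != X:
        raise TreeError("N must be a child of the root")
    C = next(c for c in tree.children[X] if c != N)
    if int(tree.parent[M]) != C:
        raise TreeError("M must be a child of the root's other child")
    S = next(c for c in tree.children[C] if c != M)

    dC = tree.branch_distance(C)
    dN = tree.branch_distance(N)
    dM = tree.branch_distance(M)
    dS = tree.branch_distance(S)
    dCn = dC + b
    valid = (0.0 < dCn < dC + dN) and (dM - dCn > 0.0)

    parent = tree.parent.copy()
    children = list(tree.children)
    parent[M] = X
    parent[N] = C
    children[X] = tuple(M if c == N else c for c in tree.children[X])
    children[C] = tuple(N if c == M else c for c in tree.children[C])
    dist = {C: dCn, N: dN + dC, M: dM - dCn, S: dS}
    return parent, children, dist, valid


def _classify_root(tree: TimeTree):
    """Root-child shapes: ('symmetric', (c1, c2)) when both are internal,
    ('asymmetric', (O, Y)) when exactly one is, None for a cherry root."""
    c1, c2 = tree.children[tree.root]
    int1, int2 = not tree.is_tip(c1), not tree.is_tip(c2)
    if int1 and int2:
        return "symmetric", (c1, c2)
    if int1:
        return "asymmetric", (c1, c2)
    if int2:
        return "asymmetric", (c2, c1)
    return None


def _asym_choice_probs(tree: TimeTree, O: int, Y: int, tC_new: float):
    """Admissible grandchild swaps for the asymmetric shape, given the
    proposed time of the surviving internal node.

    Swapping grandchild ``g`` with ``Y`` keeps the *other* grandchild and
    ``Y`` under the internal node, so it is admissible iff ``tC_new`` exceeds
    both of their ages.  When the proposed time drops below the older
    grandchild, the only admissible move hoists that grandchild to the root
    (probability 1); otherwise the two swaps are chosen with probability 0.5
    each.
    """
    g1, g2 = tree.children[O]
    tY = float(tree.times[Y])
    adm = []
    for M, other in ((g1, g2), (g2, g1)):
        if tC_new > max(float(tree.times[other]), tY):
            adm.append(M)
    return adm


def topology_proposal_ratio(tree: TimeTree, C: int, M: int, N: int,
                            tX_new: float, tC_new: float,
                            p_forward: float) -> float:
    """mu = p(reverse topology choice) / p(forward topology choice).

    The reverse of ``Exchange(M, N)`` is ``Exchange(N, M)`` applied to the
    proposed tree with the original times restored.  Its selection
    probability is 0.25 if the proposed tree's root is symmetric (blind
    uniform choice over the four grandchild swaps), else it follows the
    asymmetric admissibility rule; 0 if the reverse move could not be
    selected (the proposal is then irreversible and must be rejected).
    """
    S = next(c for c in tree.children[C] if c != M)
    tX_old = float(tree.times[tree.root])
    tC_old = float(tree.times[C])
    if not tree.is_tip(M):
        p_rev = 0.25
    else:
        # proposed tree is asymmetric: internal child C' = {S, N}, tip child M
        adm = []
        for M_rev, other in ((N, S), (S, N)):
            if tC_old > max(float(tree.times[other]), float(tree.times[M])):
                adm.append(M_rev)
        if N not in adm:
            return 0.0
        p_rev = 1.0 / len(adm)
    return p_rev / p_forward


def propose_big_pulley(tree: TimeTree, cfg: OperatorConfig, rng,
                       a: float | None = None, a2: float | None = None,
                       b: float | None = None,
                       choice: float | None = None) -> ProposalResult:
    """Re-hang the root on the underlying unrooted tree.

    Proposes a new root age, a new age for the surviving root-adjacent
    internal node, and a new split of genetic distance on the root path,
    then swaps a grandchild with the root's other child (Exchange).  All
    tip-pairwise genetic distances are conserved; the topology changes.
    """
    cls = _classify_root(tree)
    if cls is None:
        return ProposalResult.reject()
    shape, nodes = cls
    X = tree.root
    tX = float(tree.times[X])
    if a is None:
        a = cfg.draw_time(rng, tree.tree_height())
    if a2 is None:
        a2 = cfg.draw_time(rng, tree.tree_height())
    tXn = tX + a
    u = rng.random() if choice is None else choice

    if shape == "symmetric":
        c1, c2 = nodes
        C = c1 if u < 0.5 else c2
        kid_u = (u * 2.0) % 1.0
        M = tree.children[C][0 if kid_u < 0.5 else 1]
        N = c2 if C == c1 else c1
        p_fwd = 0.25
        tC = float(tree.times[C])
        tCn = tC + a2
    else:
        O, Y = nodes
        C, N = O, Y
        tC = float(tree.times[C])
        tCn = tC + a2
        adm = _asym_choice_probs(tree, O, Y, tCn)
        if not adm:
            return ProposalResult.reject()
        p_fwd = 1.0 / len(adm)
        M = adm[0] if (len(adm) == 1 or u < 0.5) else adm[1]

    S = next(c for c in tree.children[C] if c != M)
    dC = tree.branch_distance(C)
    dN = tree.branch_distance(N)
    if b is None:
        b = cfg.draw_distance(rng, dC + dN)

    parent, children, dist, valid = exchange(tree, M, N, b)
    tS = float(tree.times[S]); tM = float(tree.times[M]); tN = float(tree.times[N])
    valid = (valid and tXn > max(tCn, tM) and tCn > max(tS, tN))
    if not valid:
        return ProposalResult.reject()

    mu = topology_proposal_ratio(tree, C, M, N, tXn, tCn, p_fwd)
    if mu == 0.0:
        return ProposalResult.reject()

    times = tree.times.copy(); rates = tree.rates.copy()
    times[X] = tXn
    times[C] = tCn
    rates[C] = dist[C] / (tXn - tCn)
    rates[S] = dist[S] / (tCn - tS)
    rates[M] = dist[M] / (tXn - tM)
    rates[N] = dist[N] / (tCn - tN)

    log_green = (math.log(mu)
                 + math.log((tX - tC) / (tXn - tCn))
                 + math.log((tC - tS) / (tCn - tS))
                 + math.log((tC - tM) / (tXn - tM))
                 + math.log((tX - tN) / (tCn - tN)))

    new = TimeTree.__new__(TimeTree)
    new.taxa = tree.taxa
    new.parent = parent
    new.children = children
    new.times = times
    new.rates = rates
    return ProposalResult(new, log_green, True, changed=(C, S, M, N))


# ---------------------------------------------------------------------------
# operator classes for the scheduler
# ---------------------------------------------------------------------------

class _TreeOperator:
    """Base: operators expose ``propose(tree, rng) -> ProposalResult``."""

    name = "operator"

    def __init__(self, cfg: OperatorConfig | None = None):
        self.cfg = cfg or OperatorConfig()

    def propose(self, tree: TimeTree, rng) -> ProposalResult:  # pragma: no cover
        raise NotImplementedError


class InternalNodeOperator(_TreeOperator):
    """Constant Distance move on a uniformly chosen internal non-root node."""

    name = "constant_distance_internal"

    def propose(self, tree, rng):
        n = tree.n_taxa
        root = tree.root
        candidates = [v for v in range(n, 2 * n - 1) if v != root]
        if not candidates:
            return ProposalResult.reject()
        node = candidates[int(rng.integers(len(candidates)))]
        return propose_internal_node(tree, node, self.cfg, rng)


class SimpleDistanceOperator(_TreeOperator):
    name = "simple_distance"

    def propose(self, tree, rng):
        return propose_simple_distance(tree, self.cfg, rng)


class SmallPulleyOperator(_TreeOperator):
    name = "small_pulley"

    def propose(self, tree, rng):
        return propose_small_pulley(tree, self.cfg, rng)


class BigPulleyOperator(_TreeOperator):
    name = "big_pulley"

    def propose(self, tree, rng):
        return propose_big_pulley(tree, self.cfg, rng)


# ---------------------------------------------------------------------------
# standard auxiliary operators (used by the calibration study)
# ---------------------------------------------------------------------------

class RateWalkOperator(_TreeOperator):
    """Log-space random walk on one branch rate (changes distances)."""

    name = "rate_walk"

    def __init__(self, delta: float = 0.5):
        self.delta = delta

    def propose(self, tree, rng):
        root = tree.root
        node = int(rng.integers(tree.n_nodes - 1))
        if node >= root:
            node += 1
        u = float(rng.uniform(-self.delta, self.delta))
        rates = tree.rates.copy()
        rates[node] = rates[node] * math.exp(u)
        return ProposalResult(_share_structure(tree, tree.times.copy(), rates),
                              u, True, changed=(node,), distances_changed=True)


class RootAgeScaleOperator(_TreeOperator):
    """Scales the root's age above its older child (rates kept)."""

    name = "root_age_scale"

    def __init__(self, delta: float = 0.3):
        self.delta = delta

    def propose(self, tree, rng):
        X = tree.root
        L, R = tree.children[X]
        base = max(float(tree.times[L]), float(tree.times[R]))
        u = float(rng.uniform(-self.delta, self.delta))
        times = tree.times.copy()
        times[X] = base + (times[X] - base) * math.exp(u)
        return ProposalResult(_share_structure(tree, times, tree.rates.copy()),
                              u, True, changed=(L, R), distances_changed=True)


class NodeTimeUniformOperator(_TreeOperator):
    """Resamples one internal non-root age uniformly between its bounds."""

    name = "node_time_uniform"

    def propose(self, tree, rng):
        n = tree.n_taxa
        root = tree.root
        candidates = [v for v in range(n, 2 * n - 1) if v != root]
        if not candidates:
            return ProposalResult.reject()
        v = candidates[int(rng.integers(len(candidates)))]
        lo = max(float(tree.times[c]) for c in tree.children[v])
        hi = float(tree.times[tree.parent[v]])
        times = tree.times.copy()
        times[v] = float(rng.uniform(lo, hi))
        kids = tree.children[v]
        return ProposalResult(_share_structure(tree, times, tree.rates.copy()),
                              0.0, True, changed=(v, *kids), distances_changed=True)


class AllTimesScaleOperator(_TreeOperator):
    """Scales every internal age by a common log-space step (tips at 0)."""

    name = "all_times_scale"

    def __init__(self, delta: float = 0.2):
        self.delta = delta

    def propose(self, tree, rng):
        n = tree.n_taxa
        if np.any(tree.times[:n] != 0.0):
            return ProposalResult.reject()  # contemporaneous tips only
        u = float(rng.uniform(-self.delta, self.delta))
        times = tree.times.copy()
        times[n:] = times[n:] * math.exp(u)
        return ProposalResult(_share_structure(tree, times, tree.rates.copy()),
                              (n - 1) * u, True, changed=tuple(range(tree.n_nodes)),
                              distances_changed=True)
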