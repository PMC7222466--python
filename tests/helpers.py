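"""Shared numerical oracles for the operator tests: finite-difference
Jacobian determinants of the proposal maps, compared against the analytic
Green ratios."""

import math

import numpy as np

from constclock.operators import (OperatorConfig, propose_big_pulley,
                                  propose_internal_node,
                                  propose_simple_distance,
                                  propose_small_pulley)


def fd_det(map_fn, x0, h=1e-6):
    """|det| of the numerically differentiated map at x0 (central diffs)."""
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    J = np.empty((n, n))
    for j in range(n):
        hj = h * max(1.0, abs(x0[j]))
        xp = x0.copy(); xp[j] += hj
        xm = x0.copy(); xm[j] -= hj
        J[:, j] = (np.asarray(map_fn(xp)) - np.asarray(map_fn(xm))) / (2 * hj)
    return abs(np.linalg.det(J))


def internal_node_fd_error(tree, node, a):
    """Relative error between the analytic Green ratio and the FD |det| of
    the (t_X, r_X, r_L, r_R) -> primed map.  None if the move is invalid."""
    res = propose_internal_node(tree, node, OperatorConfig(), None, a=a)
    if not res.valid:
        return None
    L, R = tree.children[node]

    def m(x):
        t = tree.copy()
        t.times[node] = x[0]
        t.rates[node], t.rates[L], t.rates[R] = x[1], x[2], x[3]
        r = propose_internal_node(t, node, OperatorConfig(), None, a=a)
        tt = r.tree
        return [tt.times[node], tt.rates[node], tt.rates[L], tt.rates[R]]

    x0 = [tree.times[node], tree.rates[node], tree.rates[L], tree.rates[R]]
    det = fd_det(m, x0)
    return abs(det - math.exp(res.log_green)) / det


def simple_distance_fd_error(tree, a):
    res = propose_simple_distance(tree, OperatorConfig(), None, a=a)
    if not res.valid:
        return None
    X = tree.root
    L, R = tree.children[X]

    def m(x):
        t = tree.copy()
        t.times[X] = x[0]
        t.rates[L], t.rates[R] = x[1], x[2]
        r = propose_simple_distance(t, OperatorConfig(), None, a=a)
        tt = r.tree
        return [tt.times[X], tt.rates[L], tt.rates[R]]

    det = fd_det(m, [tree.times[X], tree.rates[L], tree.rates[R]])
    return abs(det - math.exp(res.log_green)) / det


def small_pulley_fd_error(tree, b):
    res = propose_small_pulley(tree, OperatorConfig(), None, b=b)
    if not res.valid:
        return None
    X = tree.root
    L, R = tree.children[X]

    def m(x):
        t = tree.copy()
        t.rates[L], t.rates[R] = x
        r = propose_small_pulley(t, OperatorConfig(), None, b=b)
        return [r.tree.rates[L], r.tree.rates[R]]

    det = fd_det(m, [tree.rates[L], tree.rates[R]])
    return abs(det - math.exp(res.log_green)) / det


def small_pulley_fd_jacobian(tree, b):
    """The full 2x2 FD Jacobian of the (r_L, r_R) map (identity expected)."""
    X = tree.root
    L, R = tree.children[X]

    def m(x):
        t = tree.copy()
        t.rates[L], t.rates[R] = x
        r = propose_small_pulley(t, OperatorConfig(), None, b=b)
        return [r.tree.rates[L], r.tree.rates[R]]

    x0 = np.array([tree.rates[L], tree.rates[R]], dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = 1e-6 * max(1.0, abs(x0[j]))
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        J[:, j] = (np.asarray(m(xp)) - np.asarray(m(xm))) / (2 * h)
    return J


def big_pulley_fd_error(tree, a, a2, b, choice):
    """Relative error for the six-variable Big Pulley map on a tree whose
    root has one internal child (the asymmetric shape)."""
    res = propose_big_pulley(tree, OperatorConfig(), None, a=a, a2=a2, b=b,
                             choice=choice)
    if not res.valid:
        return None
    X = tree.root
    C = next(c for c in tree.children[X] if not tree.is_tip(c))
    N = next(c for c in tree.children[X] if c != C)
    # M is the grandchild that ends up as a root child
    M = next(g for g in tree.children[C] if res.tree.parent[g] == X)
    S = next(g for g in tree.children[C] if g != M)

    def m(x):
        t = tree.copy()
        t.times[X], t.times[C] = x[0], x[1]
        t.rates[C], t.rates[S], t.rates[M], t.rates[N] = x[2:]
        r = propose_big_pulley(t, OperatorConfig(), None, a=a, a2=a2, b=b,
                               choice=choice)
        tt = r.tree
        return [tt.times[X], tt.times[C], tt.rates[C], tt.rates[S],
                tt.rates[M], tt.rates[N]]

    x0 = [tree.times[X], tree.times[C], tree.rates[C], tree.rates[S],
          tree.rates[M], tree.rates[N]]
    det = fd_det(m, x0)
    return abs(det - math.exp(res.log_green)) / det
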