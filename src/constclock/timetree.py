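"""Time-tree and unrooted-tree data model.

A :class:`TimeTree` is the structural core of the MCMC state: a rooted binary
topology over ``n`` taxa (``2n - 1`` nodes), a divergence time (age) per node,
and an evolutionary rate per non-root branch.  Ages are measured backwards
from the youngest tip (age 0), increasing into the past, so every parent is
strictly older than its children.  The genetic distance of the branch above
node ``i`` is ``d_i = r_i * (t_parent(i) - t_i)`` in expected substitutions
per site; it is the quantity the constant-distance operators conserve.

An :class:`UnrootedTree` carries branch lengths in substitutions per site and
is the invariant object underlying the root operators ("the unrooted tree
becomes the data" in the fixed-tree dating mode).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "UnrootedTree",
    "RootedSubstTree",
    "read_newick_timetree",
    "read_newick_unrooted",
    "write_newick",
    "midpoint_root",
    "init_times_rates_from_unrooted",
]


class TreeError(ValueError):
    pass


@dataclass
class TimeTree:
    """Rooted binary time tree with node ages and per-branch rates.

    Nodes ``0 .. n-1`` are the tips (in ``taxa`` order); internal nodes are
    ``n .. 2n-2``.  ``parent[root] == -1``; ``rates[root]`` is NaN (the root
    has no branch).
    """

    taxa: list[str]
    parent: np.ndarray
    children: list[tuple[int, ...]]
    times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rates = np.asarray(self.rates, dtype=np.float64)

    # -- basic structure -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    def is_tip(self, node: int) -> bool:
        return len(self.children[node]) == 0

    def copy(self) -> "TimeTree":
        return TimeTree(
            list(self.taxa),
            self.parent.copy(),
            [tuple(c) for c in self.children],
            self.times.copy(),
            self.rates.copy(),
        )

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`TreeError` if any invariant is violated."""
        n = self.n_taxa
        if self.n_nodes != 2 * n - 1:
            raise TreeError(f"expected {2 * n - 1} nodes, found {self.n_nodes}")
        roots = np.where(self.parent == -1)[0]
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        root = roots[0]
        for v in range(self.n_nodes):
            kids = self.children[v]
            if v < n and kids:
                raise TreeError(f"tip {v} has children")
            if v >= n and len(kids) != 2:
                raise TreeError(f"internal node {v} must have 2 children")
            for c in kids:
                if self.parent[c] != v:
                    raise TreeError("child/parent maps disagree")
                if not self.times[v] > self.times[c]:
                    raise TreeError(
                        f"node {v} (t={self.times[v]}) not older than child "
                        f"{c} (t={self.times[c]})"
                    )
            if v != root:
                if not self.rates[v] > 0:
                    raise TreeError(f"rate of branch above {v} must be > 0")

    # -- distances -------------------------------------------------------
    def branch_distance(self, node: int) -> float:
        """Genetic distance ``d = r * (t_parent - t_node)`` of the branch above ``node``."""
        p = self.parent[node]
        if p < 0:
            raise TreeError("root has no branch")
        return float(self.rates[node]) * (float(self.times[p]) - float(self.times[node]))

    def branch_distances(self) -> np.ndarray:
        """Vector of genetic distances; NaN at the root index."""
        d = self.rates * (self.times[np.maximum(self.parent, 0)] - self.times)
        d[self.root] = np.nan
        return d

    def branch_time_spans(self) -> np.ndarray:
        dt = self.times[np.maximum(self.parent, 0)] - self.times
        dt[self.root] = np.nan
        return dt

    def pairwise_distances(self) -> np.ndarray:
        """Symmetric matrix of tip-to-tip patristic distances (substitutions/site)."""
        return _patristic(self.n_taxa, self.parent, self.branch_distances(), self.root)

    def tree_height(self) -> float:
        return float(self.times[self.root])

    def tree_length_time(self) -> float:
        dt = self.branch_time_spans()
        return float(np.nansum(dt))


@dataclass
class UnrootedTree:
    """Unrooted tree: tips 0..n-1 labelled by ``taxa``; internal vertices degree 3.

    ``edges`` is a list of ``(u, v, length)`` with length in substitutions/site.
    """

    taxa: list[str]
    n_vertices: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_vertices)]
        for u, v, w in self.edges:
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj

    def validate(self) -> None:
        for u, v, w in self.edges:
            if not w > 0:
                raise TreeError(f"branch length {w} on edge ({u},{v}) must be > 0")
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if len(seen) != self.n_vertices:
            raise TreeError("unrooted tree is not connected")

    def pairwise_distances(self) -> np.ndarray:
        n = self.n_taxa
        adj = self.adjacency()
        out = np.zeros((n, n))
        for a in range(n):
            dist = np.full(self.n_vertices, np.nan)
            dist[a] = 0.0
            stack = [a]
            while stack:
                x = stack.pop()
                for y, w in adj[x]:
                    if np.isnan(dist[y]):
                        dist[y] = dist[x] + w
                        stack.append(y)
            out[a] = dist[:n]
        return out


@dataclass
class RootedSubstTree:
    """Rooted binary topology with branch lengths in substitutions/site.

    Intermediate product of midpoint rooting, before times and rates are
    assigned.  Same node-numbering convention as :class:`TimeTree`.
    """

    taxa: list[str]
    parent: np.ndarray
    children: list[tuple[int, ...]]
    lengths: np.ndarray  # substitution length of the branch above each node

    @property
    def root(self) -> int:
        return int(np.where(np.asarray(self.parent) == -1)[0][0])


def _patristic(n_tips: int, parent: np.ndarray, branch_d: np.ndarray, root: int) -> np.ndarray:
    n_nodes = len(parent)
    # distance from every tip up to each of its ancestors
    up = {}
    for a in range(n_tips):
        acc = 0.0
        v = a
        path = {v: 0.0}
        while parent[v] >= 0:
            acc += branch_d[v]
            v = parent[v]
            path[v] = acc
        up[a] = path
    out = np.zeros((n_tips, n_tips))
    for a in range(n_tips):
        for b in range(a + 1, n_tips):
            # lowest common ancestor by walking b upward
            pb = up[b]
            best = None
            for v, db in pb.items():
                if v in up[a]:
                    tot = up[a][v] + db
                    if best is None or tot < best:
                        best = tot
            out[a, b] = out[b, a] = best
    return out


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _dendropy_tree(text: str, rooting: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting=rooting,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc


def read_newick_timetree(text: str) -> TimeTree:
    """Parse newick with branch lengths interpreted as *time* spans.

    Tip ages are derived from root-to-tip path lengths (youngest tip at age
    0, supporting heterochronous tips).  Optional BEAST-style ``[&rate=x]``
    comments set branch rates; absent annotations default to rate 1.
    """
    dt = _dendropy_tree(text, "force-rooted")
    leaves = [lf for lf in dt.leaf_node_iter()]
    taxa = sorted(lf.taxon.label for lf in leaves)
    n = len(taxa)
    tip_index = {lab: i for i, lab in enumerate(taxa)}

    nodes = list(dt.preorder_node_iter())
    for nd in nodes:
        if not nd.is_leaf() and len(nd.child_nodes()) != 2:
            raise TreeError("time tree must be binary (rooted)")
    ids: dict[int, int] = {}
    next_internal = n
    for nd in nodes:
        if nd.is_leaf():
            ids[id(nd)] = tip_index[nd.taxon.label]
        else:
            ids[id(nd)] = next_internal
            next_internal += 1

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    depth = np.zeros(n_nodes)
    rates = np.full(n_nodes, np.nan)
    for nd in nodes:
        i = ids[id(nd)]
        if nd.parent_node is not None:
            p = ids[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            el = nd.edge.length if nd.edge.length is not None else 0.0
            depth[i] = depth[p] + el
            r = nd.annotations.get_value("rate")
            rates[i] = float(r) if r is not None else 1.0
    times = depth.max() - depth
    tree = TimeTree(taxa, parent, [tuple(c) for c in children], times, rates)
    tree.validate()
    return tree


def read_newick_unrooted(text: str) -> UnrootedTree:
    """Parse newick with branch lengths interpreted as substitutions/site."""
    dt = _dendropy_tree(text, "force-unrooted")
    dt.collapse_basal_bifurcation()  # degree-3 at the seed vertex
    leaves = [lf for lf in dt.leaf_node_iter()]
    taxa = sorted(lf.taxon.label for lf in leaves)
    tip_index = {lab: i for i, lab in enumerate(taxa)}
    ids: dict[int, int] = {}
    nxt = len(taxa)
    for nd in dt.preorder_node_iter():
        if nd.is_leaf():
            ids[id(nd)] = tip_index[nd.taxon.label]
        else:
            ids[id(nd)] = nxt
            nxt += 1
    edges = []
    for nd in dt.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((ids[id(nd.parent_node)], ids[id(nd)], float(nd.edge.length)))
    ut = UnrootedTree(taxa, nxt, edges)
    ut.validate()
    return ut


def write_newick(tree: TimeTree, annotate_rates: bool = True, precision: int = 12) -> str:
    """Serialize a :class:`TimeTree`; branch lengths are time spans, rates as
    ``[&rate=x]`` comments (BEAST dialect)."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def rec(v: int) -> str:
        if tree.is_tip(v):
            lab = tree.taxa[v]
        else:
            lab = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        p = tree.parent[v]
        if p < 0:
            return lab
        bl = tree.times[p] - tree.times[v]
        ann = f"[&rate={fmt(tree.rates[v])}]" if annotate_rates else ""
        return f"{lab}{ann}:{fmt(bl)}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Midpoint rooting and time/rate initialization
# ---------------------------------------------------------------------------

def midpoint_root(utree: UnrootedTree) -> RootedSubstTree:
    """Root an unrooted substitution tree at the midpoint of its diameter path.

    Ties among equal-length diameter paths are broken by the lexicographically
    smallest (sorted) taxon-name pair, so the result is deterministic.
    """
    utree.validate()
    n = utree.n_taxa
    if n < 2:
        raise TreeError("midpoint rooting needs at least 2 taxa")
    D = utree.pairwise_distances()
    best: tuple | None = None
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((utree.taxa[a], utree.taxa[b])))
            cand = (-D[a, b], key, a, b)
            if best is None or cand < best:
                best = cand
    _, _, a, b = best
    half = D[a, b] / 2.0

    # walk the a->b path, find the edge containing the midpoint
    adj = utree.adjacency()
    prev = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        for y, _ in adj[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    elen = {}
    for u, v, w in utree.edges:
        elen[(u, v)] = elen[(v, u)] = w
    acc = 0.0
    for u, v in zip(path[:-1], path[1:]):
        w = elen[(u, v)]
        if acc + w >= half - 1e-15:
            break
        acc += w
    # root splits edge (u, v): distance (half - acc) from u toward v
    cut_u = half - acc
    cut_v = w - cut_u

    # build rooted topology by hanging the tree off the new root
    root_id = utree.n_vertices  # temporary id
    children_map: dict[int, list[tuple[int, float]]] = {root_id: [(u, cut_u), (v, cut_v)]}

    def hang(x: int, banned: int) -> None:
        kids = [(y, wl) for y, wl in adj[x] if y != banned]
        children_map[x] = kids
        for y, _ in kids:
            hang(y, x)

    hang(u, v)
    hang(v, u)

    # renumber: tips keep ids, internals (incl. root) renumbered n..2n-2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    lengths = np.full(n_nodes, np.nan)
    mapping: dict[int, int] = {}
    nxt = [n]

    def newid(x: int) -> int:
        if x < n:
            return x
        if x not in mapping:
            mapping[x] = nxt[0]
            nxt[0] += 1
        return mapping[x]

    def build(x: int) -> None:
        xi = newid(x)
        for y, wl in children_map.get(x, []):
            yi = newid(y)
            parent[yi] = xi
            children[xi].append(yi)
            lengths[yi] = wl
            build(y)

    build(root_id)
    return RootedSubstTree(list(utree.taxa), parent, [tuple(c) for c in children], lengths)


def init_times_rates_from_unrooted(
    rooted: RootedSubstTree, height: float = 1.0
) -> TimeTree:
    """Assign consistent divergence times and branch rates to a rooted
    substitution tree (contemporaneous tips).

    Internal node ages are proportional to the node's level (the maximum edge
    count down to a tip), scaled into ``(0, height]``; rates are then
    ``length / dt`` so every branch's rate-time product equals its input
    substitution length exactly.
    """
    n_nodes = len(rooted.parent)
    n = (n_nodes + 1) // 2
    level = np.zeros(n_nodes, dtype=np.int64)
    # postorder over the rooted topology
    order: list[int] = []
    stack = [rooted.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(rooted.children[v])
    for v in reversed(order):
        kids = rooted.children[v]
        if kids:
            level[v] = 1 + max(level[c] for c in kids)
    times = height * level / level.max()
    rates = np.full(n_nodes, np.nan)
    for v in range(n_nodes):
        p = rooted.parent[v]
        if p >= 0:
            rates[v] = rooted.lengths[v] / (times[p] - times[v])
    tree = TimeTree(list(rooted.taxa), rooted.parent.copy(),
                    [tuple(c) for c in rooted.children], times, rates)
    tree.validate()
    return tree


def date_unrooted(utree: UnrootedTree, height: float = 1.0) -> TimeTree:
    """Midpoint-root an unrooted substitution tree and assign times/rates."""
    return init_times_rates_from_unrooted(midpoint_root(utree), height=height)
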