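"""HKY85 substitution model, pruning likelihood, and sequence simulation.

The HKY85 rate matrix has transition/transversion ratio ``kappa`` and
stationary base frequencies ``pi`` (order A, C, G, T).  ``Q`` is normalized
to one expected substitution per unit distance, so branch lengths are in
expected substitutions per site throughout.  Because the model is
time-reversible (``pi_i Q_ij = pi_j Q_ji``), the pruning likelihood is
invariant to the root's position on the underlying unrooted tree -- the
property that licenses the pulley operators.

Transition probabilities are computed from a symmetric eigendecomposition
of ``diag(pi)^{1/2} Q diag(pi)^{-1/2}`` (exact for any reversible model);
`scipy.linalg.expm` serves only as an independent oracle in the test suite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .timetree import TimeTree

__all__ = ["HKYModel", "Alignment", "transition_matrix",
           "pruning_log_likelihood", "simulate_alignment",
           "read_fasta", "write_fasta"]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC ambiguity codes -> partial-likelihood rows (full uncertainty for
# unlisted symbols and gaps)
_AMBIG = {
    "A": [1, 0, 0, 0], "C": [0, 1, 0, 0], "G": [0, 0, 1, 0], "T": [0, 0, 0, 1],
    "U": [0, 0, 0, 1],
    "R": [1, 0, 1, 0], "Y": [0, 1, 0, 1], "S": [0, 1, 1, 0], "W": [1, 0, 0, 1],
    "K": [0, 0, 1, 1], "M": [1, 1, 0, 0],
    "B": [0, 1, 1, 1], "D": [1, 0, 1, 1], "H": [1, 1, 0, 1], "V": [1, 1, 1, 0],
}


class HKYModel:
    """HKY85 model with unit expected substitution rate."""

    def __init__(self, kappa: float, pi=(0.25, 0.25, 0.25, 0.25)):
        if not kappa > 0:
            raise ValueError("kappa must be > 0")
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be 4 positive frequencies summing to 1")
        self.kappa = float(kappa)
        self.pi = pi
        self.Q = self._build_q()
        self._eig = self._decompose()

    def _build_q(self) -> np.ndarray:
        k, pi = self.kappa, self.pi
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
                Q[i, j] = (k if transition else 1.0) * pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))  # expected rate
        return Q / mu

    def _decompose(self):
        sp = np.sqrt(self.pi)
        B = (sp[:, None] * self.Q) / sp[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sp[None, :]          # U^T diag(sqrt pi)
        right = (1.0 / sp)[:, None] * U   # diag(1/sqrt pi) U
        return w, right, left

    def transition_matrix(self, d: float) -> np.ndarray:
        return transition_matrix(self, d)

    def transition_matrices(self, d: np.ndarray) -> np.ndarray:
        """Stack of P(d_i) for a vector of distances, shape (len(d), 4, 4)."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        w, right, left = self._eig
        E = np.exp(np.multiply.outer(d, w))            # (n, 4)
        return np.einsum("ik,nk,kj->nij", right, E, left)


def transition_matrix(model: HKYModel, d: float) -> np.ndarray:
    """4x4 stochastic matrix ``expm(Q d)``; identity at d = 0, rows -> pi as
    d -> infinity."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    w, right, left = model._eig
    P = (right * np.exp(w * d)[None, :]) @ left
    return np.clip(P, 0.0, None)


@dataclass
class Alignment:
    """Multiple sequence alignment: taxa labels and an (n_taxa, n_sites)
    character matrix of IUPAC symbols."""

    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/sequence count mismatch")
        lens = {len(s) for s in self.seqs}
        if len(lens) != 1 or min(lens) < 1:
            raise ValueError("sequences must be aligned and non-empty")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])

    def partials(self) -> np.ndarray:
        """Tip partial likelihoods, shape (n_taxa, 4, n_sites); cached."""
        cached = getattr(self, "_partials", None)
        if cached is None:
            out = np.ones((len(self.taxa), 4, self.n_sites))
            for i, s in enumerate(self.seqs):
                for j, ch in enumerate(s):
                    out[i, :, j] = _AMBIG.get(ch, [1, 1, 1, 1])
            self._partials = cached = out
        return cached


def read_fasta(handle) -> Alignment:
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    recs = list(SeqIO.parse(handle, "fasta"))
    return Alignment([r.id for r in recs], [str(r.seq) for r in recs])


def write_fasta(aln: Alignment, handle) -> None:
    recs = [SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.seqs)]
    SeqIO.write(recs, handle, "fasta")


def _branch_distance_vector(tree: TimeTree, distances=None) -> np.ndarray:
    if distances is not None:
        return np.asarray(distances, dtype=float)
    return tree.branch_distances()


def pruning_log_likelihood(tree: TimeTree, aln: Alignment, model: HKYModel,
                           distances=None) -> float:
    """Felsenstein pruning log-likelihood of ``aln`` on ``tree``.

    Branch lengths are the genetic distances ``r_i * dt_i`` implied by the
    state (or an explicit ``distances`` vector indexed by node).  Sites are
    independent and identically distributed (no rate heterogeneity).
    """
    order = {lab: i for i, lab in enumerate(aln.taxa)}
    if set(tree.taxa) != set(aln.taxa):
        raise ValueError("taxa mismatch between tree and alignment")
    tip_rows = [order[lab] for lab in tree.taxa]
    tip_partials = aln.partials()[tip_rows]  # aligned to tree tip ids

    d = _branch_distance_vector(tree, distances)
    root = tree.root
    d_safe = np.where(np.isnan(d), 0.0, d)
    P = model.transition_matrices(d_safe)  # (n_nodes, 4, 4)

    n_sites = aln.n_sites
    partial = np.empty((tree.n_nodes, 4, n_sites))
    partial[: tree.n_taxa] = tip_partials
    scale_log = np.zeros(n_sites)
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        acc = np.ones((4, n_sites))
        for c in tree.children[v]:
            acc *= P[c] @ partial[c]
        mx = acc.max(axis=0)
        mx = np.where(mx > 0, mx, 1.0)
        partial[v] = acc / mx
        scale_log += np.log(mx)
    site_like = model.pi @ partial[root]
    return float(np.sum(np.log(site_like) + scale_log))


def simulate_alignment(tree: TimeTree, model: HKYModel, n_sites: int,
                       rng, distances=None) -> Alignment:
    """Simulate sequences down the tree: root states from ``pi``, child
    states via per-branch transition matrices.  Reproducible given ``rng``."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    d = _branch_distance_vector(tree, distances)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(4, size=n_sites, p=model.pi)
    for v in reversed(tree.postorder()):  # preorder
        if v == root:
            continue
        P = transition_matrix(model, float(d[v]))
        # normalize rows defensively against clip round-off
        P = P / P.sum(axis=1, keepdims=True)
        u = rng.random(n_sites)
        cdf = np.cumsum(P[states[tree.parent[v]]], axis=1)
        states[v] = (u[:, None] > cdf).sum(axis=1)
    seqs = ["".join(BASES[b] for b in states[i]) for i in range(tree.n_taxa)]
    return Alignment(list(tree.taxa), seqs)
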