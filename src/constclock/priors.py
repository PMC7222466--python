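"""Prior densities for the relaxed-clock model.

The uncorrelated relaxed clock draws every branch rate independently from a
log-normal distribution with log-space mean ``m`` and log-space standard
deviation ``s``.  When used as the clock-rate prior with its *real-space*
mean constrained to 1 (the usual ucld parameterization), ``m = -s**2 / 2``.

Tree priors: constant-population coalescent (intervals with ``k`` lineages
coalesce at rate ``k (k - 1) / (2 N)``) and the Yule pure-birth process.
A flat (uniform) time prior is also provided as a reference measure for the
prior-sampling validation fixtures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .timetree import TimeTree

__all__ = [
    "LogNormalPrior",
    "CoalescentPrior",
    "YulePrior",
    "UniformTimePrior",
    "GammaPrior",
    "ClockModel",
    "PriorSpec",
    "lognormal_logpdf",
    "coalescent_log_density",
    "yule_log_density",
    "joint_prior_log_density",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal density with log-space mean ``m`` and sd ``s > 0``."""

    m: float
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError("s must be > 0")

    def logpdf(self, x: float) -> float:
        return lognormal_logpdf(x, self)

    def logpdf_vec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        ok = x > 0
        lx = np.log(x[ok])
        out[ok] = -lx - math.log(self.s) - 0.5 * _LOG_2PI \
            - (lx - self.m) ** 2 / (2.0 * self.s ** 2)
        return out

    def median(self) -> float:
        return math.exp(self.m)


def lognormal_logpdf(x: float, prior: LogNormalPrior) -> float:
    """Log-density of LogNormal(m, s) at ``x``.

    Off-support values (``x <= 0``) return ``-inf`` with a warning rather
    than raising, so the MCMC can treat them as zero-probability states.
    """
    if x <= 0:
        warnings.warn("lognormal_logpdf evaluated at x <= 0", RuntimeWarning)
        return -math.inf
    lx = math.log(x)
    return -lx - math.log(prior.s) - 0.5 * _LOG_2PI \
        - (lx - prior.m) ** 2 / (2.0 * prior.s ** 2)


@dataclass(frozen=True)
class CoalescentPrior:
    """Constant-population coalescent, population size ``N`` (time units)."""

    N: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError("N must be > 0")

    def log_density(self, internal_ages) -> float:
        return coalescent_log_density(internal_ages, self.N)

    def log_density_tree(self, tree: TimeTree) -> float:
        ages = np.sort(tree.times[tree.n_taxa:])
        return coalescent_log_density(ages, self.N)


def coalescent_log_density(internal_ages, N: float) -> float:
    """Log density of sorted internal-node ages under the constant-size
    coalescent with contemporaneous tips.

    With ``n`` tips there are ``n - 1`` coalescences; the interval during
    which ``k`` lineages are extant contributes ``(1/N) exp(-k(k-1)/2 *
    dt / N)``.  For three taxa this is exactly
    ``(1/N) e^{-(t_E - t_D)/N} * (1/N) e^{-3 t_D / N}``.
    """
    if not N > 0:
        raise ValueError("N must be > 0")
    t = np.asarray(internal_ages, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise ValueError("need at least one internal age")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("internal ages must be sorted ascending and >= 0")
    n = len(t) + 1  # number of tips
    logp = 0.0
    prev = 0.0
    for j, tj in enumerate(t):
        k = n - j  # lineages during (prev, tj)
        rate = k * (k - 1) / 2.0 / N
        logp += -math.log(N) - rate * (tj - prev)
        prev = tj
    return logp


@dataclass(frozen=True)
class YulePrior:
    """Pure-birth (Yule) tree prior with birth rate ``lam`` (1/time)."""

    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("birth rate must be > 0")

    def log_density_tree(self, tree: TimeTree) -> float:
        return yule_log_density(tree, self.lam)

    def log_density_ages(self, internal_ages) -> float:
        t = np.asarray(internal_ages, dtype=float)
        return float(len(t)) * math.log(self.lam) - self.lam * float(t.sum())


def yule_log_density(tree: TimeTree, lam: float) -> float:
    """Yule density over the labelled history's internal node ages.

    Up to a constant not involving the ages, ``log p = (n-1) log(lam)
    - lam * sum(ages)``; only relative densities matter for MCMC.  The
    density depends on the ages alone, so it is invariant under taxon
    relabelling.
    """
    if not lam > 0:
        raise ValueError("birth rate must be > 0")
    ages = tree.times[tree.n_taxa:]
    return float(len(ages)) * math.log(lam) - lam * float(np.sum(ages))


@dataclass(frozen=True)
class UniformTimePrior:
    """Improper flat reference prior on node times (log-density 0).

    Used by the prior-sampling validation fixtures, whose published
    stationary statistics carry no tree-prior dependence.
    """

    def log_density_tree(self, tree: TimeTree) -> float:  # noqa: ARG002
        return 0.0


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape alpha, scale beta) hyperprior (e.g. on ucld_stdev)."""

    alpha: float
    beta: float

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return (self.alpha - 1.0) * math.log(x) - x / self.beta \
            - math.lgamma(self.alpha) - self.alpha * math.log(self.beta)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.alpha, self.beta))


@dataclass(frozen=True)
class ClockModel:
    """Mean-one uncorrelated log-normal clock: rates ~ LogNormal(-s1^2/2, s1)."""

    ucld_stdev: float

    def __post_init__(self) -> None:
        if not self.ucld_stdev > 0:
            raise ValueError("ucld_stdev must be > 0")

    @property
    def rate_prior(self) -> LogNormalPrior:
        s = self.ucld_stdev
        return LogNormalPrior(m=-0.5 * s * s, s=s)


@dataclass
class PriorSpec:
    """Joint prior of the MCMC state.

    ``tree_prior`` is one of :class:`CoalescentPrior`, :class:`YulePrior`,
    :class:`UniformTimePrior`.  ``rate_prior`` is the branch-rate log-normal.
    Optional hyperpriors contribute when the corresponding hyperparameter is
    sampled.
    """

    rate_prior: LogNormalPrior
    tree_prior: object = UniformTimePrior()
    ucld_stdev_prior: GammaPrior | None = None
    birth_rate_prior: LogNormalPrior | None = None

    def log_density(self, tree: TimeTree, ucld_stdev: float | None = None,
                    birth_rate: float | None = None) -> float:
        return joint_prior_log_density(tree, self, ucld_stdev=ucld_stdev,
                                       birth_rate=birth_rate)


def joint_prior_log_density(tree: TimeTree, spec: PriorSpec,
                            ucld_stdev: float | None = None,
                            birth_rate: float | None = None) -> float:
    """Tree-prior term plus the sum of branch-rate log-densities plus any
    hyperprior terms.  Additive in its components; ``-inf`` propagates for
    out-of-support states."""
    tp = spec.tree_prior
    if isinstance(tp, YulePrior) and birth_rate is not None:
        tp = YulePrior(birth_rate)
    logp = tp.log_density_tree(tree)
    rp = spec.rate_prior
    if ucld_stdev is not None:
        rp = ClockModel(ucld_stdev).rate_prior
    root = tree.root
    rates = tree.rates
    m, s = rp.m, rp.s
    const = -math.log(s) - 0.5 * _LOG_2PI
    inv2s2 = 1.0 / (2.0 * s * s)
    log = math.log
    if tree.n_nodes <= 64:  # scalar loop beats numpy overhead on small trees
        acc = 0.0
        for i in range(tree.n_nodes):
            if i == root:
                continue
            r = rates[i]
            if r <= 0:
                return -math.inf
            lr = log(r)
            acc += -lr + const - (lr - m) ** 2 * inv2s2
        logp += acc
    else:
        r = np.delete(rates, root)
        if np.any(r <= 0):
            return -math.inf
        lr = np.log(r)
        logp += float(np.sum(-lr + const - (lr - m) ** 2 * inv2s2))
    if ucld_stdev is not None and spec.ucld_stdev_prior is not None:
        logp += spec.ucld_stdev_prior.logpdf(ucld_stdev)
    if birth_rate is not None and spec.birth_rate_prior is not None:
        logp += spec.birth_rate_prior.logpdf(birth_rate)
    return logp
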