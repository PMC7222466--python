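"""Metropolis-Hastings-Green engine over (time tree, rates, hyperparameters).

Acceptance of a proposal with log Green ratio ``g`` is
``min{1, exp(dlog-target + g)}``; invalid (out-of-bounds) proposals leave the
state unchanged and are counted as rejections.  Three target modes:

* ``"prior"`` -- tree prior x rate prior (x hyperpriors); no data.
* ``"fixed-distances"`` -- the unrooted substitution tree is the data; only
  distance-preserving operators are allowed and the (constant) likelihood
  term is omitted.
* ``"full"`` -- adds the HKY pruning log-likelihood, recomputed only when a
  proposal changes branch distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hky import Alignment, HKYModel, pruning_log_likelihood
from .operators import ProposalResult
from .priors import PriorSpec, joint_prior_log_density
from .stdev_operator import UcldStdevScaleOperator
from .timetree import TimeTree

__all__ = ["McmcState", "OperatorSchedule", "ChainConfig", "Trace",
           "BirthRateWalkOperator", "metropolis_step", "run_chain",
           "effective_sample_size"]


@dataclass
class McmcState:
    tree: TimeTree
    ucld_stdev: float | None = None
    birth_rate: float | None = None
    log_prior: float = math.nan
    log_like: float = 0.0

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.log_like


class BirthRateWalkOperator:
    """Log-space random walk on the Yule birth-rate hyperparameter."""

    name = "birth_rate_walk"
    preserves_distances = True

    def __init__(self, delta: float = 0.5):
        self.delta = delta

    def propose_birth(self, birth_rate: float, rng):
        u = float(rng.uniform(-self.delta, self.delta))
        return birth_rate * math.exp(u), u


class OperatorSchedule:
    """Weighted operator list; selection probability proportional to weight."""

    def __init__(self, weighted_ops):
        ops, weights = zip(*weighted_ops)
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        self.ops = list(ops)
        self.cum = np.cumsum(w / w.sum())
        self.counts = {op.name: {"proposed": 0, "accepted": 0, "invalid": 0}
                       for op in self.ops}

    def draw(self, rng):
        return self.ops[int(np.searchsorted(self.cum, rng.random()))]

    def acceptance_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts).T


@dataclass
class ChainConfig:
    mode: str                      # "prior" | "fixed-distances" | "full"
    steps: int
    sample_interval: int
    seed: int
    operators: list                # [(operator, weight), ...]
    prior: PriorSpec
    init_tree: TimeTree
    init_ucld_stdev: float | None = None
    init_birth_rate: float | None = None
    model: HKYModel | None = None
    alignment: Alignment | None = None
    monitors: dict = field(default_factory=dict)   # name -> fn(state)
    log_trees: bool = False
    audit_interval: int = 0

    def validate(self) -> None:
        errors = []
        if self.mode not in ("prior", "fixed-distances", "full"):
            errors.append(f"unknown mode {self.mode!r}")
        if self.steps < 0:
            errors.append("steps must be >= 0")
        if self.sample_interval < 1:
            errors.append("sample_interval must be >= 1")
        if self.mode == "full" and (self.model is None or self.alignment is None):
            errors.append("full mode needs model and alignment")
        if self.mode == "fixed-distances":
            for op, _ in self.operators:
                if not getattr(op, "preserves_distances", True):
                    errors.append(
                        f"operator {op.name} changes genetic distances; not "
                        "allowed in fixed-distances mode")
        try:
            self.init_tree.validate()
        except Exception as exc:
            errors.append(f"initial tree invalid: {exc}")
        if errors:
            raise ValueError("invalid chain config:\n- " + "\n- ".join(errors))


class Trace:
    """Iteration-indexed scalar samples (+ optional newick tree samples)."""

    def __init__(self, frame: pd.DataFrame, trees: list[str] | None = None,
                 acceptance: pd.DataFrame | None = None):
        self.frame = frame
        self.trees = trees or []
        self.acceptance = acceptance

    def __getitem__(self, col):
        return self.frame[col].to_numpy()

    def to_tsv(self, path) -> None:
        """Tab-separated trace in the Tracer dialect (Sample first column)."""
        self.frame.to_csv(path, sep="\t", index=False)


def _log_prior(state: McmcState, spec: PriorSpec) -> float:
    return joint_prior_log_density(state.tree, spec,
                                   ucld_stdev=state.ucld_stdev,
                                   birth_rate=state.birth_rate)


def metropolis_step(state: McmcState, schedule: OperatorSchedule, cfg: ChainConfig,
                    rng) -> McmcState:
    """One MCMC step; returns the (possibly unchanged) state."""
    if not math.isfinite(state.log_prior):
        raise RuntimeError("non-finite log target at current state (corrupt chain)")
    op = schedule.draw(rng)
    cnt = schedule.counts[op.name]
    cnt["proposed"] += 1

    new_stdev = state.ucld_stdev
    new_birth = state.birth_rate
    if isinstance(op, UcldStdevScaleOperator):
        prop, new_stdev = op.propose_hyper(state.tree, state.ucld_stdev, rng)
    elif isinstance(op, BirthRateWalkOperator):
        nb, lg = op.propose_birth(state.birth_rate, rng)
        prop = ProposalResult(state.tree, lg, True)
        new_birth = nb
    else:
        prop = op.propose(state.tree, rng)

    if not prop.valid:
        cnt["invalid"] += 1
        return state

    cand = McmcState(prop.tree, new_stdev, new_birth)
    cand.log_prior = _log_prior(cand, cfg.prior)
    if cand.log_prior == -math.inf:
        cnt["invalid"] += 1
        return state
    if cfg.mode == "full" and prop.distances_changed:
        cand.log_like = pruning_log_likelihood(cand.tree, cfg.alignment, cfg.model)
    else:
        cand.log_like = state.log_like

    log_alpha = (cand.log_prior + cand.log_like
                 - state.log_prior - state.log_like + prop.log_green)
    if log_alpha >= 0.0 or math.log(rng.random()) < log_alpha:
        cnt["accepted"] += 1
        return cand
    return state


def run_chain(cfg: ChainConfig) -> Trace:
    """Run the chain; deterministic given ``cfg.seed``.  The first trace row
    is the initial state; rows follow every ``sample_interval`` steps."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    schedule = OperatorSchedule(cfg.operators)

    state = McmcState(cfg.init_tree.copy(), cfg.init_ucld_stdev, cfg.init_birth_rate)
    state.log_prior = _log_prior(state, cfg.prior)
    if not math.isfinite(state.log_prior):
        raise RuntimeError("initial state has non-finite log prior")
    if cfg.mode == "full":
        state.log_like = pruning_log_likelihood(state.tree, cfg.alignment, cfg.model)

    rows = []
    trees: list[str] = []

    def record(it: int) -> None:
        row = {"Sample": it,
               "posterior": state.log_posterior,
               "prior": state.log_prior,
               "likelihood": state.log_like,
               "tree.height": state.tree.tree_height(),
               "tree.length": state.tree.tree_length_time()}
        if state.ucld_stdev is not None:
            row["ucld.stdev"] = state.ucld_stdev
        if state.birth_rate is not None:
            row["birth.rate"] = state.birth_rate
        for name, fn in cfg.monitors.items():
            row[name] = fn(state)
        rows.append(row)
        if cfg.log_trees:
            from .timetree import write_newick
            trees.append(write_newick(state.tree))

    record(0)
    for it in range(1, cfg.steps + 1):
        state = metropolis_step(state, schedule, cfg, rng)
        if it % cfg.sample_interval == 0:
            record(it)
        if cfg.audit_interval and it % cfg.audit_interval == 0:
            fresh = _log_prior(state, cfg.prior)
            if abs(fresh - state.log_prior) > 1e-8:
                raise RuntimeError(
                    f"audit failed at step {it}: cached log prior "
                    f"{state.log_prior} vs fresh {fresh}")
            if cfg.mode == "full":
                fl = pruning_log_likelihood(state.tree, cfg.alignment, cfg.model)
                if abs(fl - state.log_like) > 1e-8:
                    raise RuntimeError(f"audit failed at step {it}: likelihood "
                                       f"{state.log_like} vs fresh {fl}")
    return Trace(pd.DataFrame(rows), trees, schedule.acceptance_table())


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------

def effective_sample_size(series) -> float:
    """ESS = n / (1 + 2 sum rho_k), with sample autocorrelations summed until
    the first non-positive value (initial-positive-sequence truncation).

    A constant series is degenerate and reported as 1; the estimate is
    clamped to [1, n].
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        return 1.0
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        s += rho[k]
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))
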