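"""Numerical-quadrature oracles for the prior-sampling validation fixtures.

Each oracle integrates a one- (or three-) dimensional density over the
quantity a constant-distance operator moves, with the genetic distances of
the three-taxon fixture held fixed, and reports the normalized mean and
standard deviation.

Two integrand conventions are exposed through flags:

* ``include_tree_prior`` -- multiply by the constant-population coalescent
  density of the node ages.  The published integral statistics for the
  internal-node, Simple Distance and Small Pulley fixtures are reproduced
  (to ~1e-4) *without* this factor, so it defaults to off for those; the
  Big Pulley triple integral is stated with the coalescent factor and keeps
  it by default.
* ``include_fiber_jacobian`` -- divide by the time spans of the rescaled
  branches.  A Metropolis-Hastings-Green chain that uses the operators'
  Green ratios and targets ``tree_prior x prod LogNormal(r_i)`` has
  stationary fiber density proportional to that target *divided by* the
  product of the rescaled branches' time spans; with this flag the oracle
  describes exactly what such a chain samples (this is the variant the
  chain-consistency tests use).

The Small Pulley oracle is parameterized over the *tip-side* root branch
distance (time span ``t_E``), the variable whose published statistics are
reported; the internal-side distance is its complement under the conserved
sum ``D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .fixtures import FixtureSpec
from .mcmc import effective_sample_size
from .priors import coalescent_log_density

__all__ = ["OracleResult", "BigPulleyOracleResult",
           "marginal_internal_node", "marginal_root_time",
           "marginal_small_pulley", "marginal_big_pulley",
           "compare_chain_to_oracle", "OracleReport"]


@dataclass
class OracleResult:
    """Normalized 1-D density with its first two moments."""

    fixture: str
    variable: str
    grid: np.ndarray
    pdf: np.ndarray
    mean: float
    sd: float
    variant: str

    def cdf(self, x) -> np.ndarray:
        c = integrate.cumulative_trapezoid(self.pdf, self.grid, initial=0.0)
        c /= c[-1]
        return np.interp(x, self.grid, c)


@dataclass
class BigPulleyOracleResult:
    fixture: str
    t_E: OracleResult
    d_D: OracleResult
    variant: str


def _variant_name(tree_prior: bool, jacobian: bool) -> str:
    parts = ["coalescent" if tree_prior else "no-tree-prior",
             "fiber-jacobian" if jacobian else "plain"]
    return "+".join(parts)


def _moments_quad(f, lo: float, hi: float):
    z, _ = integrate.quad(f, lo, hi, limit=500)
    if z <= 0:
        raise ValueError("non-integrable settings: density mass is zero")
    m1, _ = integrate.quad(lambda x: x * f(x), lo, hi, limit=500)
    m2, _ = integrate.quad(lambda x: x * x * f(x), lo, hi, limit=500)
    mean = m1 / z
    var = m2 / z - mean * mean
    return z, mean, math.sqrt(max(var, 0.0))


def _grid_pdf(f, lo: float, hi: float, n: int = 2001):
    eps = (hi - lo) * 1e-9
    g = np.linspace(lo + eps, hi - eps, n)
    pdf = np.array([f(x) for x in g])
    z = np.trapezoid(pdf, g)
    return g, pdf / z


def _logpln(x, m, s):
    lx = np.log(x)
    return -lx - math.log(s) - 0.5 * math.log(2 * math.pi) - (lx - m) ** 2 / (2 * s * s)


def marginal_internal_node(fx: FixtureSpec, include_tree_prior: bool = False,
                           include_fiber_jacobian: bool = False,
                           n_grid: int = 2001) -> OracleResult:
    """Stationary marginal of the internal-node age ``t_D`` on ``(0, t_E)``
    with ``t_E`` fixed, under the internal-node Constant Distance move."""
    m, s = fx.rate_prior.m, fx.rate_prior.s
    tE, N = fx.t_E, fx.coalescent.N

    def logf(t: float) -> float:
        lp = (_logpln(fx.d_A / t, m, s) + _logpln(fx.d_B / t, m, s)
              + _logpln(fx.d_D / (tE - t), m, s) + _logpln(fx.d_C / tE, m, s))
        if include_tree_prior:
            lp += coalescent_log_density([t, tE], N)
        if include_fiber_jacobian:
            lp -= 2.0 * math.log(t) + math.log(tE - t)
        return lp

    peak = max(logf(t) for t in np.linspace(tE * 1e-4, tE * (1 - 1e-4), 400))
    f = lambda t: math.exp(logf(t) - peak) if 0 < t < tE else 0.0
    _, mean, sd = _moments_quad(f, 0.0, tE)
    grid, pdf = _grid_pdf(f, 0.0, tE, n_grid)
    return OracleResult(fx.name, "t_D", grid, pdf, mean, sd,
                        _variant_name(include_tree_prior, include_fiber_jacobian))


def marginal_root_time(fx: FixtureSpec, include_tree_prior: bool = False,
                       include_fiber_jacobian: bool = False,
                       n_grid: int = 2001) -> OracleResult:
    """Stationary marginal of the root age ``t_E`` on ``(t_D, inf)`` with
    ``t_D`` fixed, under the Simple Distance move.  The infinite limit is
    truncated adaptively (doubling until the mean is stable to < 1e-8)."""
    m, s = fx.rate_prior.m, fx.rate_prior.s
    tD, N = fx.t_D, fx.coalescent.N

    def logf(t: float) -> float:
        lp = (_logpln(fx.d_A / tD, m, s) + _logpln(fx.d_B / tD, m, s)
              + _logpln(fx.d_D / (t - tD), m, s) + _logpln(fx.d_C / t, m, s))
        if include_tree_prior:
            lp += coalescent_log_density([tD, t], N)
        if include_fiber_jacobian:
            lp -= math.log(t - tD) + math.log(t)
        return lp

    # lognormal factors confine the mass; pick a generous starting cutoff
    hi = tD + max(fx.d_D, fx.d_C) * math.exp(-m + 8 * s)
    peak = max(logf(t) for t in np.linspace(tD * (1 + 1e-4), hi, 800))
    f = lambda t: math.exp(logf(t) - peak) if t > tD else 0.0
    _, mean, sd = _moments_quad(f, tD, hi)
    while True:
        hi2 = tD + 2 * (hi - tD)
        _, mean2, sd2 = _moments_quad(f, tD, hi2)
        if abs(mean2 - mean) < 1e-8:
            break
        hi, mean, sd = hi2, mean2, sd2
    grid, pdf = _grid_pdf(f, tD, hi2, n_grid)
    return OracleResult(fx.name, "t_E", grid, pdf, mean2, sd2,
                        _variant_name(include_tree_prior, include_fiber_jacobian))


def marginal_small_pulley(fx: FixtureSpec, n_grid: int = 2001) -> OracleResult:
    """Stationary marginal of the tip-side root branch distance ``d_C`` on
    ``(0, D)`` with ``D = d_C + d_D`` conserved and both node times fixed.

    Times are fixed, so there is no tree-prior or change-of-variable
    ambiguity: the density is the product of the two root-branch rate
    densities."""
    m, s = fx.rate_prior.m, fx.rate_prior.s
    D = fx.d_C + fx.d_D
    span_int = fx.t_E - fx.t_D   # internal branch above D
    span_tip = fx.t_E            # branch above tip C

    def f(u: float) -> float:
        if not 0.0 < u < D:
            return 0.0
        return math.exp(_logpln((D - u) / span_int, m, s)
                        + _logpln(u / span_tip, m, s))

    _, mean, sd = _moments_quad(f, 0.0, D)
    grid, pdf = _grid_pdf(f, 0.0, D, n_grid)
    return OracleResult(fx.name, "d_C", grid, pdf, mean, sd, "plain")


def marginal_big_pulley(fx: FixtureSpec, include_tree_prior: bool = True,
                        include_fiber_jacobian: bool = False,
                        n_tE: int = 900, n_tD: int = 240, n_dD: int = 240,
                        tE_max: float | None = None) -> BigPulleyOracleResult:
    """Marginal means/sds of the root age ``t_E`` and the internal-side root
    branch distance ``d_D`` under the Big Pulley move, by nested quadrature
    of the triple integral over ``(t_E, t_D, d_D)``.

    The fixture is symmetric (all tip-pairwise distances equal), so the
    three rooted topologies share one density and pooling over them equals
    conditioning on any one.  The infinite ``t_E`` limit is truncated where
    the lognormal factors are negligible; refinement stability is exercised
    by the tests."""
    m, s = fx.rate_prior.m, fx.rate_prior.s
    N = fx.coalescent.N
    Dsum = fx.d_C + fx.d_D      # conserved root-path distance
    d_tip = fx.d_A              # cherry tip distance (d_A == d_B here)
    if tE_max is None:
        tE_max = max(Dsum, d_tip) * math.exp(-m + 6 * s) * 1.2

    tE_grid = np.linspace(1e-9, tE_max, n_tE)[1:]
    dD_grid = np.linspace(1e-12, Dsum * (1 - 1e-9), n_dD)

    def pln_vec(x):
        lx = np.log(x)
        return np.exp(-lx - math.log(s) - 0.5 * math.log(2 * math.pi)
                      - (lx - m) ** 2 / (2 * s * s))

    Z = 0.0
    S = {k: 0.0 for k in ("tE", "tE2", "dD", "dD2")}
    tE_marg = np.zeros(len(tE_grid))
    dD_marg = np.zeros(len(dD_grid))
    for i, te in enumerate(tE_grid):
        td = np.linspace(1e-9, te, n_tD)[1:-1][:, None]
        f = (pln_vec(d_tip / td) ** 2
             * pln_vec(dD_grid[None, :] / (te - td))
             * pln_vec((Dsum - dD_grid[None, :]) / te))
        if include_tree_prior:
            f = f * np.exp(np.array([coalescent_log_density([t, te], N)
                                     for t in td[:, 0]]))[:, None]
        if include_fiber_jacobian:
            f = f / (td * td * (te - td) * te)
        g_d = np.trapezoid(f, td[:, 0], axis=0)
        w = np.trapezoid(g_d, dD_grid)
        Z += w
        tE_marg[i] = w
        dD_marg += g_d
        S["tE"] += te * w
        S["tE2"] += te * te * w
        S["dD"] += np.trapezoid(dD_grid * g_d, dD_grid)
        S["dD2"] += np.trapezoid(dD_grid ** 2 * g_d, dD_grid)
    if Z <= 0:
        raise ValueError("non-integrable settings: density mass is zero")
    mean_tE = S["tE"] / Z
    sd_tE = math.sqrt(max(S["tE2"] / Z - mean_tE ** 2, 0.0))
    mean_dD = S["dD"] / Z
    sd_dD = math.sqrt(max(S["dD2"] / Z - mean_dD ** 2, 0.0))
    variant = _variant_name(include_tree_prior, include_fiber_jacobian)
    zt = np.trapezoid(tE_marg, tE_grid)
    zd = np.trapezoid(dD_marg, dD_grid)
    return BigPulleyOracleResult(
        fx.name,
        OracleResult(fx.name, "t_E", tE_grid, tE_marg / zt, mean_tE, sd_tE, variant),
        OracleResult(fx.name, "d_D", dD_grid, dD_marg / zd, mean_dD, sd_dD, variant),
        variant,
    )


# ---------------------------------------------------------------------------
# chain-vs-oracle comparison
# ---------------------------------------------------------------------------

@dataclass
class OracleReport:
    fixture: str
    variable: str
    chain_mean: float
    chain_sd: float
    oracle_mean: float
    oracle_sd: float
    mc_se: float
    ks_stat: float
    ks_threshold: float
    passed: bool

    def to_tsv(self) -> str:
        head = ("fixture\tvariable\tchain_mean\tchain_sd\toracle_mean\t"
                "oracle_sd\tmc_se\tks\tks_threshold\tpassed")
        row = (f"{self.fixture}\t{self.variable}\t{self.chain_mean:.6g}\t"
               f"{self.chain_sd:.6g}\t{self.oracle_mean:.6g}\t"
               f"{self.oracle_sd:.6g}\t{self.mc_se:.3g}\t{self.ks_stat:.4g}\t"
               f"{self.ks_threshold:.4g}\t{self.passed}")
        return head + "\n" + row


def compare_chain_to_oracle(samples, oracle: OracleResult,
                            fixture_name: str | None = None) -> OracleReport:
    """Pass iff |chain mean - oracle mean| <= 3 x (autocorrelation-adjusted
    Monte-Carlo SE) and the KS statistic against the oracle CDF is below a
    chain-length-calibrated threshold (1.63 / sqrt(ESS), ~1% level)."""
    if fixture_name is not None and fixture_name != oracle.fixture:
        raise ValueError(
            f"fixture mismatch: chain {fixture_name!r} vs oracle {oracle.fixture!r}")
    x = np.asarray(samples, dtype=float)
    ess = effective_sample_size(x)
    mean = float(x.mean())
    sd = float(x.std())
    se = sd / math.sqrt(ess)
    u = oracle.cdf(np.sort(x))
    n = len(x)
    ks = float(np.max(np.abs(u - np.arange(1, n + 1) / n)))
    ks_thr = 1.63 / math.sqrt(ess)
    ok = abs(mean - oracle.mean) <= 3.0 * se and ks <= ks_thr
    return OracleReport(oracle.fixture, oracle.variable, mean, sd,
                        oracle.mean, oracle.sd, se, ks, ks_thr, ok)
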