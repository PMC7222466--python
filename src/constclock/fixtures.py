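"""Programmatic validation fixtures: the three-taxon tree and its settings.

The fixture tree has taxa A, B (a cherry under internal node D) and C (child
of the root E).  Branch genetic distances are fixed per fixture; an MCMC
chain restricted to one constant-distance operator then explores a
low-dimensional slice whose stationary law can be checked against numerical
quadrature (:mod:`constclock.prior_oracle`).

Column convention (verified against the printed initial rates): ``d_A, d_B``
are the cherry tip branches (time span ``t_D``), ``d_C`` the root-to-tip-C
branch (span ``t_E``), ``d_D`` the internal branch (span ``t_E - t_D``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import CoalescentPrior, LogNormalPrior, PriorSpec, UniformTimePrior
from .timetree import TimeTree

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_NAMES", "three_taxon_tree"]

FIXTURE_NAMES = ("scenario1", "scenario2", "simple_distance",
                 "small_pulley", "big_pulley")


@dataclass
class FixtureSpec:
    """Fixed genetic distances, initial times and priors of one experiment.

    ``varying`` names the quantities the operator under test moves.
    """

    name: str
    d_A: float
    d_B: float
    d_C: float
    d_D: float
    t_D: float
    t_E: float
    varying: tuple[str, ...]
    rate_prior: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(-3.0, 0.25))
    coalescent: CoalescentPrior = field(default_factory=lambda: CoalescentPrior(0.3))

    @property
    def initial_rates(self) -> dict[str, float]:
        return {"A": self.d_A / self.t_D,
                "B": self.d_B / self.t_D,
                "C": self.d_C / self.t_E,
                "D": self.d_D / (self.t_E - self.t_D)}

    def prior_spec(self, include_tree_prior: bool = False) -> PriorSpec:
        tp = self.coalescent if include_tree_prior else UniformTimePrior()
        return PriorSpec(rate_prior=self.rate_prior, tree_prior=tp)


def three_taxon_tree(d_A: float, d_B: float, d_C: float, d_D: float,
                     t_D: float, t_E: float) -> TimeTree:
    """Build the ((A,B)D,C)E tree with the given distances and times."""
    taxa = ["A", "B", "C"]
    parent = np.array([3, 3, 4, 4, -1])
    children = [(), (), (), (0, 1), (3, 2)]
    times = np.array([0.0, 0.0, 0.0, t_D, t_E])
    rates = np.array([d_A / t_D, d_B / t_D, d_C / t_E, d_D / (t_E - t_D), np.nan])
    tree = TimeTree(taxa, parent, children, times, rates)
    tree.validate()
    return tree


_SETTINGS = {
    # name: (d_A, d_B, d_C, d_D, t_D, t_E, varying)
    "scenario1":       (0.1, 0.2, 0.4, 0.27, 1.0, 10.0, ("t_D",)),
    "scenario2":       (0.4, 0.8, 2.4, 1.6, 0.4, 0.8, ("t_D",)),
    "simple_distance": (0.1, 0.2, 0.4, 0.27, 1.0, 10.0, ("t_E",)),
    "small_pulley":    (0.1, 0.2, 0.4, 0.27, 1.0, 10.0, ("d_C", "d_D")),
    "big_pulley":      (0.5, 0.5, 0.3, 0.2, 5.0, 10.0,
                        ("t_D", "t_E", "d_C", "d_D", "topology")),
}


def make_fixture(name: str) -> tuple[FixtureSpec, TimeTree]:
    """Return the named fixture's spec and its initial state tree."""
    if name not in _SETTINGS:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    d_A, d_B, d_C, d_D, t_D, t_E, varying = _SETTINGS[name]
    fx = FixtureSpec(name, d_A, d_B, d_C, d_D, t_D, t_E, varying)
    return fx, three_taxon_tree(d_A, d_B, d_C, d_D, t_D, t_E)
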