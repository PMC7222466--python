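# Methods

## State, model and priors

The MCMC state is a rooted binary time tree over *n* taxa (node ages
measured backwards from the youngest tip, in arbitrary time units), one
evolutionary rate per non-root branch (substitutions/site/time), and
optional hyperparameters (the clock standard deviation *s₁*, a Yule birth
rate λ).  The genetic distance of branch *i* is *dᵢ = rᵢ Δtᵢ*
(substitutions/site); the vector of tip-pairwise genetic distances
determines the phylogenetic likelihood through the HKY85 transition
probabilities e^{Q dᵢ}, with Q normalized to one expected substitution per
unit distance.

Priors: branch rates iid LogNormal(m, s) in log space; under the mean-one
clock constraint m = −s₁²/2.  Tree priors: constant-population coalescent
(interval with k lineages coalesces at rate k(k−1)/(2N)), Yule (density ∝
λ^{n−1} e^{−λ Σ ages}, labelled-history convention — only relative densities
matter for MCMC), or an improper flat reference prior on node times.
Hyperpriors: s₁ ~ Gamma(shape 0.5396, scale 0.3819); λ log-normal with
package-default hyperparameters (ln 5, 0.3), configurable because the study
design fixes only the distribution's shape.

## The constant-distance kernels and their Green ratios

All four kernels displace a time (or a distance) by a uniform draw
(windows: half-width *w* in time, *v* in distance; defaults 10% of the tree
height / of the relevant distance sum) and then rescale the adjacent rates
so the genetic distances are unchanged.  Because the transformation from
(time, rates) to (time′, rates′) is deterministic given the draw, the
acceptance ratio needs the Jacobian determinant of that map (the Green
ratio).  For the interior-node move the map is triangular and the
determinant is the product of the time-span ratios of the three rescaled
branches; the root-shift (Simple Distance) move is the two-branch analogue;
the Small Pulley (redistributing distance across the root at fixed times)
has unit Jacobian.

The Big Pulley re-hangs the root on the underlying unrooted tree: it
proposes a new root age t_X′, a new age t_C′ for the surviving root-adjacent
internal node, a displaced split d_C′ = d_C + b of the root-path distance,
and swaps a grandchild M with the root's other child N (the *Exchange*
move), updating d_S′=d_S, d_N′=d_N+d_C, d_M′=d_M−d_C′ so all tip-pairwise
distances are conserved.  Its Green ratio is

    α_BP = μ · (t_X−t_C)/(t_X′−t_C′) · (t_C−t_S)/(t_C′−t_S)
             · (t_C−t_M)/(t_X′−t_M) · (t_X−t_N)/(t_C′−t_N)

Note the first factor uses the *current* root-to-child span t_X−t_C.  This
is what direct differentiation of the proposal map yields (the Jacobian is
triangular in the rate block), and it is the only choice consistent with the
involution identity |J(g→g′)|·|J(g′→g)| = 1 required of the self-inverse
Exchange map.  Both properties are enforced by finite-difference tests, and
with this ratio a Big Pulley prior-only chain agrees with quadrature of its
predicted stationary law to Monte-Carlo error.

Topology-selection ratio μ: with a symmetric root (both children internal)
one of the four (child, grandchild) combinations is chosen blindly with
probability 0.25.  With an asymmetric root (internal child O, tip child Y)
the admissible swaps are those whose retained grandchild is younger than the
proposed t_O′; when the proposed age drops below the older grandchild the
single admissible swap is forced (probability 1), otherwise the two swaps
are equiprobable.  μ is the ratio of the reverse to the forward selection
probability, with the reverse enumerated on the proposed tree under the
restored times; an irreversible selection (reverse probability 0) is
rejected.  For contemporaneous three-taxon trees every move is a 0.5 ↔ 0.5
swap, so μ = 1.  Moves proposing out-of-bounds times or non-positive
distances are rejected, not resampled.  A root with two tip children has no
Big Pulley move and the proposal is rejected.

The displacement kernel is pluggable in `OperatorConfig` (uniform is the
default and the only one shipped).

## The clock-standard-deviation operator

Scaling s₁ by scale = Factor + ξ(1/Factor − Factor), ξ~U(0,1), reshapes the
rate prior, so every branch rate is mapped through percentile matching
r′ = icdf_{s′}(cdf_s(r)).  For the mean-one log-normal clock this map has
the closed form ln r′ = m(s′) + (s′/s)(ln r − m(s)), m(s) = −s²/2, giving
per-rate derivative (s′/s)(r′/r); the generic scipy cdf/icdf route is kept
as a cross-check oracle.  The log-Hastings term is −ln(scale) plus the sum
of the per-rate log-derivatives, the product running over the tree's actual
2n−2 branch rates (the dimension of the transformed variables — enforced by
the finite-difference test).  Non-finite mapped rates reject the proposal.

## Prior-sampling validation: oracles and what a correct chain samples

On the three-taxon fixture (cherry (A,B) under D, tip C under root E), a
chain restricted to one operator explores a low-dimensional slice at fixed
genetic distances, and its stationary density can be computed by numerical
quadrature.  Two integrand conventions are implemented:

* **Published convention** (default for the internal-node, root-age and
  distance-split oracles): the product of the log-normal densities of the
  state's branch rates, with no tree-prior factor and no change-of-variable
  factors.  This convention reproduces the published integral statistics of
  those three fixtures to ~1e-4 (e.g. internal-node Scenario 1 mean/sd
  3.2669/0.5553).  The distance-split (Small Pulley) oracle is
  parameterized over the tip-side root branch, the variable whose published
  statistics are reported.
* **Sampler convention** (`include_fiber_jacobian=True`, tree prior
  matching the chain config): detailed balance shows that a chain using the
  operators' Green ratios and targeting tree-prior × ∏ LogNormal(rᵢ) has
  stationary fiber density proportional to that target **divided by the
  time spans of the rescaled branches**.  This variant is what the
  chain-consistency tests compare against, and chains for all four
  operators match it to 3 Monte-Carlo standard errors plus a KS check.

The two conventions coincide for the distance-split fixture (times fixed)
but differ for the time-moving fixtures; validation fixture chains
therefore default to the flat time reference prior, under which their means
fall within ~5% of the published chain means.  The Big Pulley triple
integral is implemented as stated, coalescent factor included, with
truncation of the root-age axis where the log-normal factors are negligible
and grid-refinement stability tested; its published row is not reproduced
by any convention that reproduces the other fixtures, and the package
reports the integral's honest value.

Quadrature: adaptive Gauss–Kronrod (scipy) for the 1-D oracles with the
integrand exponentiated around its log-scale peak; tensor-grid trapezoid
for the 3-D oracle; normalization checked to 1e-8; infinite upper limits
doubled until the mean is stable to 1e-8.

## MCMC engine

Operator drawn ∝ weight each step; invalid proposals count as rejections;
acceptance min{1, exp(Δ log target + log Green ratio)}.  Target modes:
prior-only; fixed-distances (an unrooted substitution tree is the data —
only distance-preserving operators are admitted and the constant likelihood
is omitted); full posterior (HKY pruning likelihood, recomputed only when a
proposal changes genetic distances — the constant-distance kernels never
do).  An audit mode recomputes cached log-densities from scratch every k
steps and fails the run on disagreement above 1e-8.  Traces are pandas
frames writable as Tracer-dialect TSV.  ESS uses the
initial-positive-sequence truncation, n/(1+2Σρ_k), clamped to [1, n]
(constant series report 1); it is cross-checked against arviz within the
accuracy such truncation rules share.

## Fixed-unrooted-tree dating

When branch lengths in substitutions/site are treated as known, the unrooted
tree is the data.  The root is placed at the midpoint of the diameter path
(ties broken by the lexicographically smallest taxon pair, for determinism);
internal node ages are set proportional to each node's level (maximum edge
count to a tip below), scaled into (0, H] for a configurable initial height
H; rates are then length/Δt, making every rate–time product match its input
length exactly.  Any consistent assignment would do as a chain
initialization; this one is simple and always valid.  The mode is restricted
to contemporaneous tips.

## Scaled well-calibrated study

Design: 20 taxa, 50 replicates, 100 sites, 30 000-step chains (thinning 10,
25% burn-in) — sizes chosen so the whole study runs in minutes on one CPU
while each chain reaches effective sample sizes of a few dozen for the
monitored scalars.  Per replicate: s₁ and λ drawn from their hyperpriors
(s₁ floored at 1e-4 to avoid a numerically degenerate clock), a Yule tree,
iid rates, an HKY alignment (κ = 2.4751, π = (0.2193, 0.2268, 0.3007,
0.2531)); inference runs with the constant-distance kernels plus standard
rate/time/hyperparameter operators, with the topology fixed at its
simulated truth.  Two moves update the clock standard deviation, both with
rate quantile matching: the bounded scale kernel and an independence kernel
that redraws s₁ from its prior (percentile matching transports the rate
density exactly, so its acceptance reduces to the likelihood ratio — an
effective global jump when the data constrain s₁ weakly).  Conditioning a
credible set on part of the simulated truth leaves its coverage exactly
nominal, and keeps the study within the fixed-topology operator set (the
topology-changing kernel is validated by the prior-sampling fixtures
instead).  Monitored: tree height, tree length,
s₁, λ, mean branch rate; each parameter's 95% HPD coverage must fall in the
exact central 99% binomial band around 0.95.  Replicates whose posterior
ESS falls below a floor are flagged in the result rather than silently
pooled.  A negative control (analysis birth rate fixed 10× too high)
drives tree-height coverage out of the band.

What the generator does *not* emulate: rate variation across sites,
substitution-model misspecification, alignment error, non-contemporaneous
sampling, and topology uncertainty in the analysis — passing coverage here
validates the sampler and its Green ratios, not robustness of the model to
real-data violations.

## Numerical choices and limitations

* Transition probabilities via the symmetric eigendecomposition
  diag(π)^{1/2} Q diag(π)^{-1/2} (exact for reversible models); `expm` is
  only a test oracle.  Pruning partials are per-node rescaled to avoid
  underflow; ambiguity codes and gaps are full-uncertainty partials.
* Operator tuning defaults (windows, scale boldness) favour ~20–50%
  acceptance on the study's tree sizes; they are constructor arguments, not
  adaptive.
* Yule simulation conditions on n via exponential inter-coalescent gaps;
  heterochronous tips are supported by the data model and kernels but not
  by the midpoint-rooting mode or the calibration study.
* The engine is single-chain, non-adaptive, and pure Python/numpy: built
  for verification-scale problems (tens of taxa), not genome-scale
  inference.
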