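# Methods

This note records the models implemented in `biomespec`, the numerical
choices behind them, and what the synthetic data do and do not emulate.

## Biome coding

Input is a long-format overlap table: per species and climatic
dominion, the fraction of the species' range inside the dominion
(`range_fraction`) and the fraction of the dominion covered by the
species (`dominion_fraction`). A catalog maps every dominion to exactly
one of the ten Walter biome classes; montane dominions carry the biome
whose altitudinal vegetation series they mirror and are flagged as
montane.

Presence coding applies two rules after aggregating dominions to
biomes:

* **range rule** — the summed range fraction in the biome is ≥ 0.15;
* **dominion rule** — any *single* dominion of the biome is covered to
  ≥ 0.50 (the rule is evaluated per dominion, never on pooled
  dominions, because it exists to rescue wide-ranging species whose
  presence in one small dominion falls below the 15% cut).

Both thresholds are inclusive and configurable. The 15% rule is
evaluated per biome after aggregation (the natural reading when a biome
comprises several dominions). Range fractions are *not* renormalized to
sum to one: a range may straddle area outside every cataloged dominion.
Species coded into zero biomes are excluded with a logged report rather
than aborting the run — real datasets are screened so this does not
occur, but synthetic and exploratory inputs can trigger it.

A species is flagged a *montane dweller* when at least one of its
presences disappears if montane dominions are ignored. This enables a
sensitivity reanalysis that drops mountain-range species — relevant for
high-latitude biomes such as the tundra, whose occupant list is
otherwise diluted by species that reach tundra-like vegetation only on
mountains.

BSI is the row sum of the presence matrix; mean BSI therefore equals
total richness over species count (an identity the tests exploit:
with per-biome richness (44, 93, 48, 35, 26, 44, 29, 45, 40, 10) over
197 species, mean BSI = 414/197 ≈ 2.10). Specialization classes are
stenobiomic (BSI = 1), semi-eurybiomic (1 < BSI < 5) and extreme
eurybiomic (BSI ≥ 5).

## Richness-constrained null model

The null hypothesis is that specialists are randomly scattered across
biomes and clades, while each biome keeps its observed species richness
(biomes legitimately differ in richness, so a null that equalized them
would test the wrong thing). Per replicate, biome *b* receives `sp_b`
distinct species drawn uniformly without replacement from the *N*
species, independently across biomes. 10000 replicates are the default.

Conventions, each pinned by an exact counterpart:

* **Percentages are conditioned on occupancy**: the denominator of the
  BSI frequency is the number of species occupying ≥ 1 biome in that
  replicate. Under this convention the replicate-mean frequency matches
  the Poisson-binomial mass conditioned on ≥ 1 biome (27.5% at BSI = 1
  for the reference marginals); without conditioning it would match the
  unconditional mass (≈ 25.1%), which is not what the summary tables
  report.
* **Per-biome specialist fraction**: among the `sp_b` occupants of
  biome *b*, the share with BSI = 1. Its exact null expectation is
  `∏_{j≠b} (1 − p_j)` with `p_j = sp_j / N`. Biomes with `sp_b = 0` are
  reported as undefined (NaN), not zero.
* **Empirical p-values** use inclusive counting with no pseudo-count:
  `P(null ≥ obs)` and `P(null ≤ obs)` are both stored; the reported
  tail is chosen against the null mean (or forced by the caller).
  Values below 1/replicates display as `<0.001`; exact fractions are
  kept in the tables. No multiple-testing correction is applied.
* **Clade analyses** re-randomize only the clade's species against the
  clade-level richness marginals.

The analytic oracle (Poisson-binomial by convolution, specialist
product formula) is computed by a different route than the simulator
and the two are required to agree within Monte Carlo error; on systems
small enough to enumerate (≤ 3 biomes, ≤ 4 species) the simulator is
checked against exhaustive enumeration. Note the two references differ
at small *N*: the replicate-mean of a ratio is not the conditional
per-species probability (for two singleton biomes over two species the
enumerated mean specialist share is 50% while the conditional
Poisson-binomial gives 2/3); at *N* ≈ 200 the ratio bias is far inside
Monte Carlo error, which is why both cross-checks are valid at their
respective scales.

## Trait-dependent diversification

The speciation rate is a function of a continuous trait (BSI treated as
quantitative):

| shape    | λ(x)                                                        | free parameters |
|----------|-------------------------------------------------------------|-----------------|
| constant | λ₀                                                          | 3 (λ₀, μ, σ²)   |
| linear   | max(0, λ₀ + s·x), clamp reported                            | 4               |
| sigmoid  | λ₁ + (λ₀ − λ₁) / (1 + exp(r·(x − x_mid)))                   | 6               |
| modal    | λ₁ + (λ₀ − λ₁)·exp(−(x − x_mid)²/(2w²))                     | 6               |

Extinction μ is constant (trait-independent) in every model: trees of
extant species carry weak information about extinction, so only the
speciation shape is inferred. Trait evolution is Brownian with
diffusion rate σ² (trait²/Myr) and, in drift variants (+1 parameter),
a deterministic tendency φ (trait/Myr; positive φ pushes toward higher
BSI, i.e. toward generalism). The four-parameter logistic and Gaussian
bump are the conventional forms matching these parameter counts.

### Likelihood

Two functions propagate tipward-to-rootward on a trait grid: E(x, t),
the probability a lineage leaves no surviving descendants, and D(x, t),
the density of the observed subtree. Per time step, operator splitting
applies

1. the birth–death reaction with λ frozen at each grid point, using the
   closed-form constant-rate solution for E (Riccati equation) and a
   trapezoidal-in-E exponential multiplier for D;
2. Brownian diffusion + drift as a convolution executed in Fourier
   space, with the Gaussian kernel's transform evaluated analytically —
   so a kernel narrower than the grid spacing is never under-resolved.
   E and D are packed into one complex FFT per step; D is zero-padded,
   E is padded with a linear bridge between its edge values so circular
   wrap-around injects no spurious mass.

Tips initialize D as a Gaussian of sd 0.25 trait units (configurable)
around the observed value — BSI is an integer count, and a narrow
kernel both represents that discreteness honestly and stabilizes the
grid — and E = 0 (extant species sampled with certainty). Internal
nodes combine daughters as D_left · D_right · λ(x). The root averages
D over the grid weighted by the relative likelihood of each trait value
("obs"), switchable to flat weighting for sensitivity. D is
renormalized each step with the log-mass accumulated separately;
likelihoods are unconditioned on survival. A stem (root) edge, when
present, is propagated like any branch.

Numerical guardrails: grid bounds must bracket the tip traits with a
3-kernel-sd margin (default grid: data range padded by 3 trait units);
if more than a configurable fraction (10⁻³) of D mass reaches the
outermost cells, the likelihood aborts with advice to widen the grid;
E is clipped to [0, 1] after each convolution.

Correctness is anchored by two independent references implemented
without the grid: for trait-independent rates the likelihood factorizes
exactly into the constant-rate birth–death tree likelihood (closed-form
E and D updates per branch) plus the Brownian tip-trait likelihood
(Gaussian belief propagation), and the grid result must match their sum
to 10⁻³; a fine-grid/small-step reference integrator pins small-tree
values, and doubling the resolution while halving the step must move
lnL by less than 10⁻².

### Fitting and model comparison

Bounded quasi-Newton (L-BFGS-B) on transformed parameters (positive
parameters in log space), from three moment-derived starts: a Yule-type
speciation guess (n−1 over total branch length), σ² from tip-trait
variance over tree height, x_mid at the trait median, with the rate
contrast varied across starts. Callers can inject extra starts; the
pipeline seeds every non-constant shape with the fitted constant
optimum embedded as a degenerate start, so a nested shape never scores
below its special case. Fits that produce no finite likelihood are
flagged and excluded from comparisons with a warning. Models are
compared by AIC = 2n − 2 lnL per tree; per-tree ΔAIC ≤ 2 is flagged as
a tie, and across trees the mean/range/sd of lnL, AIC and ΔAIC plus
each model's best-model frequency are reported.

### Simulator and polytomies

The forward simulator advances in fixed steps (default 0.05 Myr): each
lineage speciates with probability λ(x)·dt, dies with μ·dt, and takes a
Brownian increment φ·dt + √(σ²·dt)·z. Extinct subtrees are pruned and
unifurcations suppressed; complete extinction raises a flagged error so
callers can retry with a fresh seed (the dataset-level generator does
this automatically). Polytomies are resolved by uniform sequential
random pairing; each new internal branch takes a length uniform on
(0, ε_max · min(child branch lengths)] (ε_max = 0.5) subtracted from
the two grouped children, conserving every root-to-tip depth exactly.
This is a deliberately simple randomization — it propagates resolution
uncertainty without attempting Bayesian branch-length inference.

## Synthetic data

The presence-matrix generator emulates the statistical skeleton of a
global ruminant-like assemblage: N = 197 species, per-biome richness
(44, 93, 48, 35, 26, 44, 29, 45, 40, 10), and a specialist excess
calibrated so ≈ 40% of species are stenobiomic (the mixture weight
solving w + (1 − w)·p₁ = target, with p₁ the null's conditional
specialist probability). Sampling is a mixture — specialist with
probability w, otherwise the independent null occupancy conditioned on
≥ 1 biome — followed by an exact-marginal repair that moves single
presences from over-full to under-full biomes (BSI-preserving moves
preferred; surplus drops take from generalists so no row empties).
Montane species are synthesized by routing a configurable share of
presences through montane-flagged dominions. The overlap-table
generator inverts presence coding: each presence triggers exactly one
rule (the 15% rule only while the per-species unit range budget
allows), absences stay strictly below both thresholds, and the round
trip through coding reproduces the matrix exactly.

What the synthetic data do **not** emulate: spatial autocorrelation of
ranges, phylogenetic signal in biome occupancy, realistic clade
assignments (labels are random), or any species-level correspondence
with a real assemblage. Passing tests therefore demonstrate that the
machinery is correct under the stated statistical structure, not that
any particular biological dataset will show the same effects.

## Problem sizes and defaults

Defaults mirror the analysis this package operationalizes: 10000 null
replicates, 100 polytomy resolutions, thresholds 0.15/0.50, trait grid
of 128 points with 0.1 Myr steps. The built-in validation experiments
use sizes chosen to keep the full suite fast on a single CPU while
retaining statistical power: recovery experiments run 60-tip trees
(10 seeds for the sigmoid sign-recovery, 5 constant-data control
trees) on 96-point grids with 0.5 Myr steps; the closed-form
factorization identity uses a 20-tip tree on a 256-point grid. Under
the decreasing sigmoid (λ₀ = 0.17, λ₁ = 0.018, x_mid = 4.61) the
recovery simulations use x₀ = 4.0, σ² = 0.3, r = 1.0 and μ = 0:
because fast-speciating specialists dominate such trees, the tip-trait
cloud must straddle the inflection for the high-trait plateau to be
identifiable, and these values give trait spans comparable to the
empirical BSI range (1–8) while leaving ~15% of tips above x_mid.

## Known limitations

* The likelihood assumes contemporaneous tips when sharing E across
  sister branches at a node (E is averaged); for strongly
  non-ultrametric trees this is an approximation.
* μ is fixed trait-independent by design; trait-dependent extinction is
  out of scope.
* The linear shape's zero-clamp makes λ non-smooth at the clamp point;
  the optimizer handles it but standard errors at the clamp are not
  meaningful.
* Random polytomy resolution explores topology, not branch-length,
  uncertainty.
* At 60-tip scale the AIC preference for the generating non-constant
  shape holds in a majority of replicates but not uniformly; single
  small trees can favor the constant model, which is expected behavior
  of AIC under weak signal rather than a defect.
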