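# Methods

This note records the models pcmkit implements, the conventions chosen
where several are defensible, and what the test suite's synthetic data
do and do not establish.

## Tree model and I/O

Trees are rooted with non-negative edge lengths.  Node ids follow the
convention used across the comparative-methods ecosystem — tips `1..n`
in file order, root `n+1`, internals assigned in preorder — so that
node-indexed output tables (ancestral states, MCMC node columns) can be
compared row-for-row with tables printed by other implementations.

The SIMMAP dialect stores a per-edge list `{state,len:state,len:...}`
in place of the branch length.  Internally, segments always run rootward
→ tipward.  Because writers differ on this orientation, the parser
detects it globally: it counts state mismatches between each edge's
rootward end and its parent edge's tipward end under both readings and
keeps the orientation with fewer, so files from either convention load
correctly.  Zero-length edges are legal and act as instantaneous
(transition probability = identity).

Birth–death simulation is Gillespie sampling with exponential waiting
times.  Under a taxon-number stop, once the target count is reached all
pending edges are extended by one further exponential holding time, so
the returned ultrametric tree has exactly *n* tips at a uniformly random
point of the final inter-event interval — the convention the MCCR null
expects.  Total extinction is signalled and retried up to a cap.

## Extended Mk engine

The likelihood is computed by post-order pruning with per-node
rescaling of partial likelihoods (log scaling factors accumulate into
the log-likelihood), which keeps 250+-tip, 4+-state problems well away
from underflow.  Transition matrices use an eigendecomposition fast
path — one decomposition of **Q** per likelihood evaluation, then
exp(**Q**t) for all edges by a vectorized similarity transform —
guarded by a condition-number check (< 1e8) with scipy's
scaling-and-squaring `expm` as the fallback for defective or
ill-conditioned **Q**.  Rows of each propagator are clipped at zero and
renormalized to absorb round-off.

Root priors: flat (default), fixed, or FitzJohn nuisance weighting, in
which the prior is the normalized vector of root partial likelihoods
(so the root contribution is Σ L<sub>i</sub>²/Σ L<sub>j</sub>).  The
flat default reproduces published binary-trait model tables; FitzJohn
is the default for hidden-rates fits, matching common practice.
Ambiguous or missing tip states are level sets with partial likelihood
1 on each allowed level.

Fitting optimizes log rates with L-BFGS-B inside the box
[1e-12, 100 × tree height].  The default start is (number of levels) /
(total edge length); extra starts draw rates from an exponential around
that value.  Simple Mk models use one start; expanded models default to
10, since hidden-rates surfaces are multimodal.  Degrees of freedom =
number of rate classes; AIC = 2·df − 2·logL.

Marginal ancestral reconstruction uses the standard two-pass
(inside/outside) algorithm; model-averaged reconstructions are Akaike-
weighted sums of per-model marginals.  Joint reconstruction is
max-product dynamic programming with ties broken toward the lowest
state index, making output deterministic.

## State-space expansions

*Polymorphic model.*  The unordered space contains **all** non-empty
subsets of the monomorphic levels; the ordered space only contiguous
runs of the level order, with polymorphism gained or lost at the ends of
the run.  These choices are the unique pair consistent with the free-
rate counts of the published three-level habitat analysis (12 ordered
vs 18 unordered ARD classes).  Conditions are canonicalized ("b+a" ≡
"a+b").  The transient model ties all polymorphism-increasing moves to
one class and all decreasing moves to a second.

*Hidden-rates model.*  Each observed level carries `ncat` rate
categories labelled with trailing stars (O, O\*, …).  Hidden moves step
between adjacent categories of a level; observed moves connect equal
categories of different levels, or — under the umbral variant — only
the labile (unstarred) conditions.  Tip data spread over the hidden
levels of the observed state.  `ncat=1` reduces exactly to ARD.  These
models are weakly identified: the tests therefore assert rate
*orderings* (labile vs inert) on simulated data, not point recovery.

## Stochastic character mapping

Node states are drawn jointly: the root from prior × partial
likelihoods, then each child conditionally on its sampled parent using
the stored down-pass partials.  Edge paths are simulated conditional on
their endpoints by forward rejection sampling (cap 1000 tries per
edge), falling back to uniformization — the number of virtual jumps is
drawn from its exact conditional distribution, the jump chain
backwards-filtered, and jump times placed as uniform order statistics.
Sampled maps are therefore exact draws from the conditional
distribution of histories; the suite checks node-state frequencies
against the analytic marginals at binomial-error tolerance.  With a
model table, each replicate first draws its generating model with
probability equal to the Akaike weight; the chosen index is recorded
per map for auditability.

HPD intervals on change counts are the shortest contiguous interval of
the empirical distribution containing ≥ 95% of the sample (no kernel
smoothing).  `density_map` evaluates each edge at res+1 evenly spaced
points; `ltt_by_state` accumulates per-state lineage counts on the
pooled event grid with difference arrays (right-continuous steps), so
states always sum to the plain LTT.

## Continuous traits

Blomberg's K uses the GLS mean ā = (1′C⁻¹1)⁻¹1′C⁻¹x and the ratio of
observed to Brownian-expected (MSE₀/MSE); the permutation p-value
counts permutations with K ≥ K_obs with the observed arrangement
included as the first draw.  Pagel's λ rescales off-diagonal
covariances; σ² and the root are profiled analytically and λ is
optimized over ten subintervals of [0, λ_max], where λ_max = (max tip
height)/(max internal-node height) — the largest value keeping C(λ)
consistent with tip heights.  The LR test against λ = 0 uses χ²₁.

`fast_anc` solves the branch-length-weighted harmonic system on the
tree, whose solution equals the phylogenetic mean of the tree re-rooted
at each node (the test suite checks this equivalence explicitly, and
against the conditional-normal closed form).  Optional variances use
the REML rate ((x−ā)′C⁻¹(x−ā)/(n−1)) and the universal-kriging
correction for the estimated mean.

`anc_bayes` is one-parameter-at-a-time Gaussian random-walk Metropolis
over (σ², root, node values), σ² proposals reflected at zero.  Defaults:
exponential prior on σ² with mean 1000; Normal(0, 1000) node priors;
all proposal variances 0.01 × tree height × the initial GLS rate
estimate (n−1 divisor); sampling every 100 generations with generation
0 recorded, so a chain of ngen generations yields ngen/100 + 1 rows and
a 20% burn-in of a 500,000-generation chain keeps 4001 of 5001 samples.
The likelihood conditions tips and non-root internal values jointly on
the root parameter via the node-augmented covariance matrix.

## Multivariate and variable rates

`evolvcv_lite` stacks the two traits trait-major and builds the
covariance Σ<sub>regimes</sub> R<sub>r</sub> ⊗ C<sub>r</sub>, where
C<sub>r</sub> is the shared path length spent in regime r; root means
are profiled by GLS.  Rates are optimized as logs, correlations on
(−1, 1); each model keeps the best of 10 random restarts.  Degrees of
freedom count rate/correlation parameters plus the two means: 5/7/6/8
for models 1–4 with two regimes.

`multirate_bm` maximizes
logL(x | σ²-scaled covariance) + λ_pen · logP(ln σ² | BM, unit rate),
over one ln σ² per node (tips included).  The rate of an edge is the
**logarithmic mean** (σ²₁−σ²₂)/(ln σ²₁−ln σ²₂) of its endpoint rates —
the average of a geometric interpolation along the edge — and the
penalty is the BM log-density of the non-root values given the root's,
with the rate process's own scale absorbed into λ_pen.  This objective
was validated against an independent implementation on a 30-tip
simulation (data terms agree to < 1e-3).  As λ_pen → ∞ all rates
collapse to the single-rate ML σ̂² (asserted at 1% tolerance).  The
optimization is L-BFGS-B over 2n−1 parameters with numerical gradients;
it is intended for trees of up to a few hundred tips.

`phyl_pca` eigendecomposes V = (X−ā)′C⁻¹(X−ā)/(n−1) (or its
correlation); scores are GLS-centred data rotated by the eigenvectors,
and loadings are trait–score correlations computed with C-weighting.
Component signs are arbitrary; tests compare absolute values.

## Diversification

γ is computed from the inter-node intervals g<sub>k</sub> (the time with
k lineages); the two-tailed p is 2Φ(−|γ|).  The MCCR test simulates
pure-birth trees with round(n_obs/ρ) tips, prunes a uniform random set
back to n_obs, and doubles the empirical tail on the observed side of
the null median (capped at 1, no plus-one adjustment).

The birth–death likelihood is the Nee reconstructed-process form with
sampling fraction ρ folded into p₀ and p₁, conditioned on the crown age
and on both crown lineages being sampled, plus the (N−1)! ordering
constant; `fit_yule` is the same code path with d pinned at 0 (scalar
search on (0, 2·q̂/ρ], q̂ = (n−2)/total edge length), and `fit_bd`
multi-starts a Nelder–Mead search from (1.1·q̂, 0.1·q̂).  The exported
likelihood callable evaluates any (b, d), enabling surface plots and
profile checks.

## Synthetic data and what the tests show

The fixture generator produces pure-birth (optionally birth–death)
trees rescaled to unit height, Mk characters (default binary ER with
q = 1 — one expected change per tree height, a realistic signal level
for a 100-tip comparative study), and unit-rate BM traits, all
deterministic given the seed.  It emulates clean, fully sampled,
correctly measured data: no measurement error, no topological
uncertainty, no among-site/among-trait correlation beyond what the
models state.  Passing tests therefore establish internal correctness
(estimators recover generating parameters; samplers match analytic
marginals), not robustness to the misspecifications real data carry.

Statistical test sizes were chosen to keep the default suite within a
few minutes while leaving comfortable error margins: 500 replicates for
the mean-K check, 600–800 trees for the γ null, 10–20 replicates for
rate-recovery medians, 300 trees for parser round-trips, 8 × 200-tip
replicates (3 restarts) for the hidden-rates ordering check, and
10,000 maps for the node-frequency/marginal comparison.  Benchmark
reproductions run on the published datasets exported from the locally
installed R library and assert the printed values at their printed
precision (log-likelihoods ±0.01–0.05, rates ±1–2%, stochastic
quantities ±0.02–0.05).

Known limitations: no NEXUS input, unrooted trees or reticulation;
`evolvcv_lite` handles exactly two traits; `multirate_bm` has no
built-in cross-validation for λ_pen (users supply it and should compare
several values); hidden-rates and polymorphic likelihood surfaces are
multimodal, so restart counts below the defaults can return local
optima; the birth–death extinction rate is weakly identified on trees
of a few hundred tips (expect ±40% even at n = 500).
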