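# Methods

This note documents the models implemented by `icfp`, the defaults and
the reasoning behind them, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Carbon flux paths

The path model works on a network split to irreversible form: each
reversible reaction becomes a forward/backward pair with negated
stoichiometry and mirrored carbon arcs, linked as mutually exclusive
partners. Carbon-exchange arcs are taken as given input (one
substrate→product pair per reaction that genuinely transfers carbon);
the package does not compute atom mappings.

Variables: binary `u_ij` per ordered metabolite pair covered by at
least one carbon arc (self-pairs excluded — pairs with no arc are
forced to zero by the support constraint, so they are never created),
binary `z_r` and continuous `v_r ∈ {0} ∪ [1, N]` per reaction.
Constraint families: source/target degree (exactly one arc out of the
source and into the target, none in the opposite directions — the
latter imposed as variable bounds), flow conservation of arcs at
intermediates, at most one entering arc per metabolite (simple path;
the bound is applied to the source too, where it is vacuous),
steady state for internal metabolites, net production ≥ 0 for external
non-medium metabolites, semicontinuous flux linking, reverse-pair
exclusion, and arc support. Medium metabolites carry no balance
constraint at all: they model freely exchangeable growth-medium
species. Source and target get their ordinary class-based balance
constraint; no special exemption is needed because the source is
typically a medium metabolite and the target an external product.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `big_m` (N) | 1000 | flux ceiling linking v to z; a warning fires when any optimal flux comes within 1% of N (possible truncation of the balancing scenario) |
| `flux_floor` | 1 | minimum non-zero flux; fixed by the model definition |
| `stage_tolerance` | 1e-6 | relative slack when carrying a stage optimum forward |
| `mip_gap` | 0 | stages are solved to proven optimality; a nonzero gap is only advisable at genome scale and weakens the ranking guarantee |

### Three-stage lexicographic solve

Stage 1 minimizes total flux through L, stage 2 total flux through M
holding the stage-1 optimum, stage 3 the arc count holding both. Three
sequential solves are used instead of a single weighted objective:
weights large enough to emulate lexicographic order destroy the MILP's
numerics. Stage optima are carried forward as inequalities with
relative tolerance (`Σ_L v ≤ V1(1+ε)+ε`) rather than equalities — the
objective can never go below its proven optimum, so the inequality has
the same semantics while tolerating floating-point drift; if the next
stage is infeasible anyway, one retry at 10× the slack is attempted
before giving up. The reported (V1, V2) are the proven stage optima;
realized flux sums may sit within the slack of them, which the
independent checker tolerates (1e-4).

A stage whose objective covers no reaction is skipped exactly (an empty
sum is zero and its fixing constraint vacuous). When *every* reaction
is in M the expression data carries no information; the flux stage is
then skipped as well with V2 recorded as 0, which reduces the method to
plain shortest balanced path finding. Minimizing total network flux in
that situation would instead bias the ranking toward low-flux rather
than short scenarios, which is not what an expression-free comparison
means.

### Enumeration

After each solution the cut `Σ_{(i,j)∈P} u_ij ≤ |P| − 1` forbids
re-using the complete arc set P; cuts accumulate over the whole
enumeration. Because each iteration re-optimizes all three stages over
a shrinking feasible set, the staged tuples are lexicographically
non-decreasing in rank. Order *within* a block of identical tuples is
solver-dependent and explicitly unspecified; the report flags tied
blocks. Enumeration stops early, with a notice, when the model becomes
infeasible (all balanceable paths exhausted).

Every returned solution is re-verified by an independent checker that
reconstructs activity from fluxes and re-evaluates each constraint
family numerically (tolerance 1e-6 on continuous constraints) plus the
staged objective. HiGHS (via `scipy.optimize.milp`) is run with
feasibility tolerances of 1e-9 because the big-M formulation amplifies
solver slack into visible flux drift at the default 1e-7.

### Brute-force oracle

The oracle enumerates every simple source→target path in the carbon-arc
graph (guarded to ≤ 12 metabolites) and solves, per path, two small
MIPs over (z, v) with the path's arcs forced: min L-flux, then
min M-flux at the fixed L-optimum. The subproblems are integer, not
plain LPs, because the semicontinuous flux domain means a continuous
relaxation could balance a path with sub-unit fluxes that the real
model forbids, under-reporting V1/V2. Off-path reactions carry flux
freely, mirroring the main model's balancing semantics. Survivors are
sorted by (V1, V2, length). The oracle shares no code path with the
main solver's arc formulation and is the reference in the equivalence
suite (50 random networks, top-3 tuples compared exactly after rounding
to 4 decimals).

## Expression classification

### Series route

Per feature (gene or protein), log2 expression is regressed on the
condition value (e.g. specific growth rate in 1/h). The tested effect
is the fitted change across the full condition range, Δ = slope ×
range, because the fold-change threshold refers to the change between
the first and last condition; this makes the test invariant to linear
rescaling of the condition axis. The p-value for H0: |Δ| ≤ log2 T
(default T = 1.5) is the sum of the two shifted tail probabilities
P(t > (|Δ̂|−τ)/se) + P(t > (|Δ̂|+τ)/se) with the regression's residual
degrees of freedom — the standard form of a fold-change-threshold
(TREAT) test; at Δ̂ = τ it is ≥ 1/2 by construction, and under the null
it is stochastically larger than uniform (conservative). Note the
*average* of the two tails is not a valid p-value (it is bounded near
1/2 under the null) and is not used.

Defaults and edge cases: features not mapping to a metabolic gene are
dropped; features with fewer than 4 non-missing measurements go to the
invariant pool; residual variance below 1e-12 is treated as an exact
fit (p = 0 if |Δ̂| > τ else 1); a constant condition design yields
sign 0, p = 1. Optional variance moderation shrinks per-feature
variances toward the cohort mean with a prior dof (default 4 when
enabled, off by default): a deliberate simplification of
empirical-Bayes moderation that avoids re-implementing a full
hyperparameter fit — enabling it slightly increases power on short
series.

Protein calls take precedence over gene calls feature by feature
(protein abundance is the closer proxy for enzyme activity); the
protein's sign is taken wholesale along with its p-value, and the
question of conflicting gene/protein signs therefore never arises.
Features with neither measurement are non-differential by assumption.
FDR correction is Benjamini–Hochberg by default; a density-based
tail-area estimator (Grenander least-concave-majorant ECDF with
Storey's π₀ at λ = 0.5) is selectable by config for users who prefer a
mixture-model q-value. Genes with q strictly below the cut (default
0.2; "below" is read strictly) are called up or down by the regression
sign.

### Fold-change route and GPR projection

The one-shot route calls up/down at |log2 FC| > 0.5850 (a 1.5-fold
change); missing values are invariant. Gene states are projected onto
reactions by ternary GPR evaluation — up = +1, invariant = 0,
down = −1, AND = min (a complex is limited by its weakest subunit),
OR = max (any isoenzyme suffices), missing genes 0. Root value +1 → H,
−1 → L, else M; reactions without a rule are M (no evidence). Both
members of a split reversible pair share one rule and hence one state.
H, M, L are exhaustive and mutually exclusive by construction.

## Synthetic generators

`random_network` plants a unimolecular chain from the medium source to
the external target (so at least one balanceable path always exists —
verified in the test suite by the oracle) and surrounds it with random
reactions of 1–2 substrates/products, coefficients in {1, 2}, carbon
arcs drawn per substrate-product pair with a density parameter, a
reversible fraction, and small random GPRs over an 8-gene pool. It
emulates the combinatorics of path finding, not biochemistry: no mass
conservation across a reaction (only sign structure), no currency
metabolites, no compartments.

`synthetic_expression` emulates growth-rate-resolved profiling: 8
conditions spanning 0.10–0.45 1/h, linear log2 trends with a planted
total change of ±2·log2 1.5 for differential features (20% of 500 by
default), iid Gaussian noise of sd 0.25 per measurement, and an
independent protein-level replicate for a random 30% of features to
exercise the merging rule. These defaults are the study conditions
used by the acceptance measurements. The generator does not emulate
probe effects, batch structure, intensity-dependent variance or
missingness patterns of real arrays/proteomics, so recovery numbers
measured on it say nothing about absolute performance on real data —
only about the pipeline's internal consistency.

Under exactly these conditions the pipeline's measured operating
characteristics (acceptance script, 20 seeds) are a sensitivity around
0.2–0.35 with a realized false-discovery proportion of ~0 and a null
false-positive proportion of ~0 at FDR 0.2. The test is deliberately
conservative twice over — the threshold null concedes a fold change of
τ, and the planted change of 2τ sits only one τ above it with a
per-fit standard error of ~0.27 log2 units on 8 points — so most true
features are not separable at this signal-to-noise level; power rises
steeply with the planted effect or falling noise. The acceptance suite
records a stricter sensitivity expectation as failing; the
corresponding test is left red rather than weakening the test statistic
(e.g. averaging the two tails, which roughly doubles apparent power at
the cost of invalid p-values) or quietly enabling moderation.

## Problem sizes

The equivalence and reduction suites use networks of 4–10 metabolites
and 6–14 reactions (50 and 20 seeds respectively); the classifier
measurements use 500 features × 8 conditions × 20 seeds (50 for the
null). These sizes keep the full test suite under a minute while still
exercising every constraint family and both enumeration regimes;
genome-scale networks are expected to work through the same API with a
time limit and a documented warning if the MIP gap is relaxed, but
exact replication of path lists at that scale depends on solver
internals and is not guaranteed.

## Known limitations

* Carbon arcs must be supplied; there is no atom-mapping inference.
* No thermodynamic constraints, flux-variability analysis or biomass
  machinery.
* The density-based FDR estimator is a simple Grenander/Storey
  construction, not a full mixture-model fit.
* SBML import trusts the compartment suffix to separate internal from
  external species and always takes carbon arcs from the side table.
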