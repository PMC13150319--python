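# Methods

## The scientific question and the data model

A furcating xylem network — parent conduits dividing into `b` narrower
daughters at discrete branching events along the stem — couples conduit
number to conduit diameter: where diameters shrink distally, counts must
rise.  A constant-number ("widened pipe") architecture instead keeps the
same conduits running the length of a branch segment and maintains
conductance by widening them toward the base.  The discriminating datum is
a branch sampled at two cross-sections: the count of functional conduits
and their mean lumen diameter at the base and at the tip, plus each
section's path distance from the shoot apex (`BranchRecord`).  Canonical
units are μm for diameters and cm for lengths; loaders convert via unit
hints so the regression and prediction modules never see mixed units.
For externally branched stems the tip count is the sum over daughter
twigs, flagged `branched`; furcation concerns the internal
number–diameter relationship, so such records are analysed together with
unbranched ones.

Validation distinguishes hard errors (non-positive counts or diameters,
tip at or beyond the base distance) from warnings (a base diameter below
the tip diameter, which contradicts the widening expectation but is
representable).  Rows failing hard checks are skipped at load time and
reported with their file row numbers, never silently dropped.

## Standardized major axis regression

With both counts formed concurrently by the cambium in response to the
same leaf area, neither variable causes the other; the model-II (SMA)
estimator `b = sign(r)·s_y/s_x` is therefore used for the
`log₁₀ N_tip ~ log₁₀ N_base` line.  All analysis variables are log₁₀
transformed — counts, diameters and lengths arise multiplicatively, and
the furcation hypothesis itself is a statement about a log–log slope.

Inference follows standard SMA theory:

- slope CI: `b·(√(B+1) ± √B)` with `B = F₁₋α;1,n₋₂·(1−r²)/(n−2)`;
- slope test against `b₀`: zero-correlation test between the residual
  scores `y − b₀x` and axis scores `y + b₀x` on `n−2` df (this is the
  test whose inversion yields the CI, so p at a CI edge equals α);
- intercept CI from `Var(ȳ − b·x̄) = SSR/((n−2)·n) + x̄²·Var(b)` with
  `Var(b) = b²(1−r²)/(n−2)` and a t quantile.  The intercept is reported
  but is not central: an additive offset is not a furcation signature.

Degenerate inputs (zero variance, n < 3) raise rather than return NaNs.
The estimator is cross-checked in the tests against an independent oracle:
numeric minimization of the summed point–line triangle areas (for fixed
slope the optimal intercept is `ȳ − b·x̄`, reducing the problem to a 1-d
search per sign branch).

The segment-length analysis is an ordinary multiple regression
(statsmodels OLS) of `log₁₀ N_tip` on `log₁₀ N_base` and segment length;
cumulative furcation predicts a positive length coefficient.  Segment
length enters as log₁₀(cm) by default, consistent with the global log
transform; a `log_length=False` flag fits raw cm instead, since summary
tables elsewhere label this predictor simply "segment length".  The
widening analysis pools both sections of every branch (2n points) and
regresses `log₁₀ diameter` on `log₁₀ distance-from-apex` by OLS; each
point uses its own section's apex distance.  No multiple-testing
correction is applied across the three regressions.

## Furcation baselines

All four baselines share `N_tip = N_base·bⁿ` with symmetric bifurcation
(b = 2) by default and `n` kept continuous — the defining formulas yield
non-integer event counts and no rounding rule is imposed (an integer
display mode exists).  Products are carried in log₁₀ space; raw counts
are materialized only below 10¹⁵ (a 1 m segment with 3 cm spacing already
implies 2³³ ≈ 10¹⁰-fold proliferation).

- **Fixed spacing:** `n = L_segment/L_b`, swept over L_b = 3–30 cm in 3 cm
  steps in the reference comparison.
- **Geometric contraction:** internode lengths `L₀, λL₀, …, λⁿL₀` sum to
  the segment length.  Fixing the distalmost internode at `L_n` (default
  1 cm) gives `L₀ = (1−λ)·L_segment + λ·L_n` and
  `n = log_λ(1 − L_segment(1−λ)/L₀) − 1`.  That expression is evaluated
  through its algebraic equivalent `n = log_λ(λL_n/L₀) − 1`, which avoids
  catastrophic cancellation when `L_n ≪ L_segment`; the two forms are
  identical by the definition of L₀.  Segments no longer than L_n get
  n = 0 rather than an error.  λ defaults to 0.7 (daughter internodes 70%
  as long as mothers).
- **Conservation rules:** with `R = d_base/d_tip` (equal to the radius
  ratio), da Vinci's area rule gives `N_tip = R²·N_base` and Murray's law
  `N_tip = R³·N_base`.  R ≤ 1 still yields a prediction, flagged
  `no-widening`.

`compare_scenarios` reports, per scenario, the fraction of branches whose
prediction strictly exceeds the observed tip count (ties excluded) and
the median log₁₀ prediction/observation ratio.

## Phylogenetic RMA with Pagel's λ

Under Brownian motion the trait covariance between two species is the
shared root-to-ancestor path length; Pagel's λ scales the off-diagonal
entries (0 = independent species, 1 = full Brownian covariance).  The fit
replaces sample moments with their phylogenetic counterparts: GLS means
`â = (1ᵀC_λ⁻¹1)⁻¹1ᵀC_λ⁻¹T` and evolutionary covariance
`V = (T−1â)ᵀC_λ⁻¹(T−1â)/(n−1)`; the RMA slope is
`sign(V_xy)·√(V_yy/V_xx)` and the intercept `â_y − slope·â_x`.  A single
λ common to both traits maximizes the bivariate Brownian log-likelihood
`−½(nm·log2π + n·log|V| + m·log|C_λ| + m(n−1))` on [0, 1]; with the
(n−1)-denominator V plugged in, the quadratic form collapses to the
constant m(n−1), so the profile in λ is unchanged relative to the ML
(n-denominator) convention and estimates agree with the standard R
implementation (verified in the tests against a frozen `phyl.RMA`
reference fit to 10⁻⁵).

Numerics: all solves go through a Cholesky factor of C_λ (never an
explicit inverse); the likelihood can be nearly flat near λ = 0, so an
11-point grid scan brackets the optimum before bounded scalar
minimization (xatol 10⁻⁸), and the bracket edges are kept if they match
the interior optimum (the bounded optimizer cannot land exactly on 0 or
1).  Trees must be ultrametric within 10⁻⁶ relative tip-depth spread;
tips without trait data are pruned (no imputation).  On a star phylogeny
the fit reduces exactly to ordinary RMA.  Tree construction and dating
are out of scope — the module consumes any user-supplied Newick
chronogram, and counts are log₁₀ transformed by default to match the
standard analysis.

## Synthetic data generator

`simulate_dataset` emulates the sampling design: one branch per species
(112 by default); basal apex distance log-uniform over 60–770 cm; the tip
section a uniform 5–30 cm below the apex; diameters
`10^(1.2 + 0.2·log₁₀dist + ε)`, ε ~ N(0, 0.25), independently at the two
sections, spanning roughly 10–300 μm; basal counts log-uniform over
10^1.5–10^4 (a generator default — the source data's count range is not
published); and tip counts equal to base counts times `10^N(0, σ_n)`
under the null, or a furcation scenario's prediction when one is
injected.  Counts are rounded with a floor of 1.

The default σ_n = 0.06 makes the null nearly exact (r² ≈ 0.99 given the
wide count range); matching the empirical r² ≈ 0.82 would require
σ_n ≈ 0.34 with these defaults.  The default is kept small deliberately:
it is a calibration knob, not an estimated quantity, and the recovery
properties tested (CI coverage, type-I rate, power, widening-slope
recovery) do not depend on its exact value.  Diameter noise is
independent between the two sections of a branch by default, so a
noiseless run (σ_d = 0) is the construction that guarantees base
diameters exceed tip diameters on every record; with noise on, occasional
inversions occur and are surfaced as validation warnings — real branches
likely share within-branch factors this independence ignores.

`simulate_tree` draws pure-birth trees, extends every tip edge by the
exponential waiting time to the next (uncommitted) speciation — the
simulator otherwise stops exactly at the n-th split, leaving zero-length
sibling edges and a singular covariance — and rescales depth to 1.
`simulate_bm_traits` draws bivariate traits with covariance
`kron(rate_matrix, C_λ)` via the two Cholesky factors.  Every generator
is a pure function of (config, seed).

What passing tests on these data do and do not show: they demonstrate
that the estimators recover known truth under the model's own
assumptions (lognormal noise, independent species under the null, exact
power-law widening), not that those assumptions hold in real stems; the
published summary statistics can be reproduced by pointing the pipeline
at the deposited measurement table (see README).

## Problem sizes and determinism

The recovery batteries use 500 null replicates (coverage and type-I
rate), 200 replicates for power, and 100 replicates of 200-tip trees per
λ value — sizes at which the Monte-Carlo error of each reported rate is
well below the decision bands, while a full run stays around a minute.
Pipeline outputs are byte-deterministic given the inputs; every CSV/JSON
embeds the configuration hash (excluding output paths) and seed.

## Known limitations

- The widening regression treats the two points of a branch as
  independent observations, as in the reference analysis; a mixed model
  would be more efficient but is out of scope.
- Conservation predictions use 30-conduit mean diameters; within-section
  diameter distributions are not modelled.
- Asymmetric branching ratios and hydraulic conductance/carbon-cost
  computations are not implemented.
- λ̂ estimates at the boundary (0 or 1) are returned as exact boundary
  values; no standard error for λ̂ is reported.
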