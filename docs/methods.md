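# Methods

## The question the package answers

Two conditions (strains, species, treatments) of the same biological
pathway produce different time courses. Two very different causes can
explain that: the pathway's *mechanism* changed (rewiring — altered
regulatory connections or kinetic constants), or only its *input* changed
(a different initial state driving the same mechanism into a different
trajectory). `pathq` discriminates the two by fitting dynamical-system
models comparatively and testing whether one shared mechanism suffices.

## Model

Each pathway node `i` is a variable `x_i(t)`; its rate of change is an
additive nonlinear function of its topology-parents:

    dx_i/dt = beta_0 + sum_{l in L_i} beta_l x_l
            + sum_{(q1,q2) in Q_i} beta_q x_q1 x_q2
            + sum_{s in S_i} beta_s x_s/(x_s + h_s) + noise.

Linear terms encode proportional regulation, quadratic terms (self-pairs
allowed) combinatorial/mass-action effects, and the saturating
Michaelis-Menten-form term approximates transcription-activation kinetics:
`h_s` is the regulator abundance producing half occupation (the term is
exactly 0.5 at `x_s = h_s`). A Hill exponent of 1 is the simplest form with
the half-occupation property; steeper response curves are absorbed
approximately by combinations of terms.

Model complexity `m(i)` counts every fitted quantity: 1 for the intercept,
1 per linear or quadratic coefficient, and 2 per sigmoidal term
(coefficient plus the fitted `h`). Counting `h` is the default because it
is estimated from data and must cost a degree of freedom; a flag
(`Caps.count_h=False`) reproduces the 1-per-sigmoid convention for
sensitivity checks.

## Derivative estimation

The regression target is the rate of change, estimated per variable by a
cubic penalized smoothing spline (residual sum of squares + lambda times
integrated squared curvature; `scipy.interpolate.make_smoothing_spline`).
Lambda is chosen by generalized cross-validation independently per variable
(variables differ by orders of magnitude in scale and noise). Smoothing is
always done within one condition; pooling happens later at the
regression-sample level, never at the smoothing level, because the two
conditions are different dynamical regimes. With exactly 4 distinct time
points (the minimum accepted) GCV is not identifiable and an interpolating
cubic spline is used.

## Partial pathway reconstruction

For each child a shared active-term structure is selected from the
super-pathway topology and four models are fitted:

* `P1`, `P2` — the same term structure, coefficients fitted separately per
  condition (heterogeneous pair);
* `P12` — one fit to the pooled samples (homogeneous model);
* `P0` — a constant equal to the time-averaged derivative over the pooled
  sample (null model, complexity 1).

Coefficients are ordinary least squares of the estimated derivative on the
term design matrix. Each `h_s` is profiled over a fixed grid of 17
quantiles of the parent's positive observed values between the 5th and
95th percentiles, refitting the linear coefficients per grid point and
keeping the global minimiser. Inside the selection loop one shared grid per
(child, parent), computed from the *pooled* sample, is used for all four
fits; this guarantees the nesting RSS1+RSS2 <= RSS12 <= RSS0 exactly
(the heterogeneous pair can always realise the pooled model's `h`), rather
than only up to grid mismatch. The standalone single-fit API defaults to
the fitted data set's own quantiles.

The term structure is chosen to minimise the p-value of the per-child
total-strength statistic

    F_t(i) = [(RSS0 - RSS1 - RSS2)/u] / [(RSS1 + RSS2)/v],
    u = 2 m(i) - 1,  v = n1 + n2 - 2 m(i),

over all candidate structures with at most `Caps.max_terms` terms
(default 3; exhaustive enumeration, switching to greedy forward selection
past `Caps.max_candidates` candidates). Ties are broken toward smaller
complexity, then enumeration order. Candidates with non-positive `v` are
skipped. p-values are compared on the natural-log scale: at low noise the
F statistics are enormous and plain survival probabilities underflow to 0,
which would silently reduce "minimise the p-value" to the tie-break.

### Numerics of the search

A child's selection loop evaluates thousands of tiny OLS problems. All
candidate columns (intercept; one column per linear/quadratic term; one
column per sigmoid term per grid value of `h`) are materialised once per
(child, data set), unit-normalised, and their Gram matrix precomputed, so
each candidate's normal equations are an indexed batch solve. A ridge of
1e-8 on the normalised Gram keeps near-collinear candidates finite during
the search only; the finally selected structure is refitted by `lstsq` on
the raw columns (rank-deficient designs fall back to the minimum-norm
solution with a warning), so reported RSS values carry no ridge bias.
Negative abundances — possible after additive noise — contribute zero
occupancy to sigmoid columns.

## Q statistics and the decision

Per-pathway sums RSS_hom = sum RSS12(i), RSS_het = sum RSS1(i)+RSS2(i),
RSS_null = sum RSS0(i) and total complexities m1, m2, m12, m0 (= number of
nodes) give

    Q_d = [(RSS_hom  - RSS_het)/u_d] / [RSS_het/v_d]   (heterogeneity)
    Q_c = [(RSS_null - RSS_hom)/u_c] / [RSS_hom/v_c]   (homogeneity)
    Q_t = [(RSS_null - RSS_het)/u_t] / [RSS_het/v_t]   (total strength)

with u_d = m1+m2-m12, u_c = m12-m0, u_t = m1+m2-m0, v_d = v_t =
n1+n2-(m1+m2), v_c = n1+n2-m12. The identity

    u_t Q_t RSS_het/v_t = u_c Q_c RSS_hom/v_c + u_d Q_d RSS_het/v_d

(the decomposition of total strength into homogeneity plus heterogeneity)
holds algebraically and is verified numerically by
`check_decomposition`; the audit over 1000 random fitted pathways observes
residuals at the 1e-14 level. A pathway whose pooled model degenerates to
the null model (every child intercept-only) has u_c = 0; Q_c is reported
as 0 with p_c = 1. Negative numerators cannot occur by construction and
are clamped (with a warning) only as a guard against floating-point noise.

Under standard regression normality assumptions the three statistics follow
asymptotic F distributions with their printed degrees of freedom; upper-tail
p-values come from `scipy.stats.f` (with log-scale variants kept alongside
for ranking nearly-noiseless cases). The decision rule at level alpha:
*differential* if p_d <= alpha (regardless of homogeneity), else
*conserved* if p_c <= alpha, else *insufficient evidence*.

### Permutation significance

To be robust against non-normal residuals and dependent nodes, p_d and p_c
can instead be calibrated by permutation: draw |pathway| nodes uniformly
without replacement from the whole system, independently swap each sampled
node's condition-1/condition-2 series with probability 0.5, reconstruct on
the induced sub-topology, and record Q*_d, Q*_c; the empirical p-value uses
the add-one rule (1 + #{Q* >= Q_obs})/(B+1), so the smallest attainable p
is 1/(B+1). Default B = 1000; seeds are mandatory.

Two implementation points matter. First, draws that reproduce the observed
comparison verbatim — the tested node set with no node, or every node,
swapped — are redrawn: the identity permutation is already accounted for by
the add-one rule, and when the system is no larger than the pathway such
no-ops would otherwise receive probability 2^-(p-1) and put an irreducible
floor of about 2^-(p-1) on the attainable p-value (for a 5-node pathway
the floor would sit above alpha = 0.05, making the test powerless by
construction). Second, per-node swapping requires both conditions to share
one time grid; with unequal grids the chimeric regression samples would
misalign and the test refuses to run. Across permutations only a handful of
distinct per-child fits occur (child, induced parents, swap pattern of
child and parents), so fits are memoised; 200 permutations of a 5-node
cascade cost well under a second.

### Per-node heterogeneity

Each molecule's own rewiring signal is the Q_d restricted to the
sub-pathway of the molecule and its immediate parents — computed from that
child's fit record alone, with u = m(i), v = n1+n2-2m(i). This profiles
which nodes respond to the rewiring.

## The simulation benchmark

Ground truth generators perturb a base ODE system:

* **conserved** — identical parameters; each initial value offset by an
  independent Uniform(L, U) draw (changed input, same mechanism);
* **differential** — every parameter multiplied by an independent
  Normal(mu, sigma) draw; initial state untouched (changed mechanism).

Time courses are sampled at 100 uniformly spaced points on a
system-specific grid and Gaussian noise is added per variable at
SNR(dB) = 10 log10(Var_signal/Var_noise) — the variance convention, so
0 dB means noise power equal to signal power and a constant series gets no
noise. Negative post-noise abundances are kept; smoothing and the
zero-clipped sigmoid columns absorb them. Variants whose integration fails
or blows up are redrawn (logged), keeping numerically unstable ground
truth out of the ROC, and each (base, variant) pair receives fresh noise.
ROC curves score each pair by the asymptotic p_d on the log scale
(Q-method) or by the dispersion index (comparator); AUC is computed by
the standard threshold sweep (scikit-learn).

### Built-in systems and their study settings

| system | variables | grid | mu, sigma | L, U |
|---|---|---|---|---|
| cdc2-cyclin cell-division cycle (rapid-equilibrium parameterisation) | 6 | 1..100, dt 1 | 3, 0.1 | 0.001, 0.005 |
| Sel'kov glycolytic oscillator | 2 | 1..100, dt 1 | 1.8, 0.1 | 0.03, 0.05 |
| chaotic Lotka-Volterra predator-prey | 3 | 0.3..30, dt 0.3 | 1.1, 0.01 | 0.004, 0.010 |
| 5-node additive cascade (calibration) | 5 | 0.1..10, dt 0.1 | 2, 0.1 | 0.1, 0.5 |

The cell-cycle and glycolysis rows follow the published benchmark setups
for those process classes; the chaotic system uses near-unity multipliers
(a chaotic system is maximally parameter-sensitive) with initial offsets
matching its conserved phase-plane example, and the cascade's offsets are
large enough to excite a visible transient. The LV analysis runs with
`max_terms=4` because each of its child equations has four generating
terms (linear self plus three quadratics); the default cap of 3 cannot
represent the generating family.

### The chaotic Lotka-Volterra default

The 3-variable predator-prey system is the generalized-LV form
dx_i/dt = x_i (r_i + sum_j a_ij x_j) with Gilpin's classic one-prey/
two-predator "spiral chaos" food-web parameterisation, affinely rescaled
(state / 200, time x 50) so abundances are unit-order, the oscillation
period is a few time units, and trajectories from initial states differing
by ~5e-3 diverge macroscopically around t = 10-15 (largest Lyapunov
exponent ~ 0.5 per rescaled time unit, Benettin renormalisation estimate).
The rescaling leaves the generalized-LV form intact. The predator
abundance dips many decades between blooms, so the system's integration
uses an essentially-zero absolute tolerance (1e-150) to keep error control
relative all the way down; ordinary atol lets the dips cross zero and blow
up. Parameters are configurable (`LVParams`) for users who want their own
chaotic setting.

## The bundled 5-node cascade

`example_additive_dsm()` is a fixed stable cascade X1 -> ... -> X5 mixing
all three term families with first-order decay — the calibration workhorse.
It is exactly inside the fitted model family, so it separates questions of
statistical calibration from questions of model misspecification.

## What the synthetic studies do and do not show

The generators emulate: mechanistic rewiring as coefficient changes,
input changes as initial-state changes, measurement noise as additive
white Gaussian per variable, and regular sampling. They do not emulate:
biological replicate variability, non-Gaussian or autocorrelated
measurement error, missing observations, unobserved confounding nodes, or
topology misspecification. Passing these studies therefore demonstrates
correctness and calibration of the machinery on data generated by the
model class it assumes (plus the published nonlinear ODE systems above),
not performance on any particular experimental data set.

## Parameter-recovery study

Recovery is assessed on the bundled cascade simulated noiselessly from
several random initial states (a single run settles to steady state and
leaves coefficients barely identified); per-run spline derivatives are
pooled and each child refitted with its true term structure. Because `h`
is estimated by grid profiling, an off-grid generating `h` is *not*
jointly identifiable with the intercept to 5% (the intercept absorbs the
sub-grid-cell h offset); the study therefore snaps the generating `h` to
the profiling grid first — mirroring how the estimator quantises — and
recovers all coefficients to ~1-4% (residual error traceable to spline
derivative estimation) and `h` to well under one grid cell.

## Known limitations

* **Stiff systems at negligible noise.** When a model contains a
  rapid-equilibrium pair (e.g. the cell-cycle model's phospho-exchange
  with rate constants ~1e6), the true derivative carries spikes that 100
  uniformly spaced samples cannot resolve. The spline's systematic error
  is then state-predictable within one condition, and at very high SNR
  (~100 dB) it dominates the residual: conserved pairs (same mechanism,
  different phase) show strong *apparent* heterogeneity, and the
  asymptotic per-pair ranking can even invert relative to genuinely
  rewired pairs. Moderate noise (20 dB and below) restores the expected
  behaviour because measurement error swamps the aliased structure. The
  permutation test is the principled guard for decisions on such data;
  for ROC-style ranking studies at extreme SNR the benchmark results
  should be read with this caveat.
* **Permutation power with a small system.** When the tested pathway *is*
  the entire system, the pseudo-pathways are condition-swap chimeras of
  the two compared data sets; under a genuine rewiring those chimeras mix
  the two mechanisms and carry large Q*, so the permutation null is
  inflated under the alternative and the test loses power (type-I
  calibration is unaffected — it is verified by the packaged calibration
  study). The scheme is designed for the setting where the system is much
  larger than the pathway (e.g. a whole transcriptome), where the null
  draws are unrelated node sets. Ranking studies (ROC) therefore use the
  asymptotic p_d.
* The decision rule reports raw p-values; correcting across many pathways
  (FDR) is left to the caller.
* Only two conditions are supported; the framework extends to more
  heterogeneous models but that is not implemented.
* Sub-grid resolution of `h` is not attempted; confidence intervals on
  coefficients are not reported.

## Study sizes

The packaged validation studies use: 20+20 pairs per system and SNR for
the ROC benchmark, 30+30 pairs for the chaotic-LV power study, 200
replicates x 200 permutations for type-I calibration, 1000 random
pathways for the decomposition audit, and 4 x 200-point noiseless runs
for parameter recovery (dense enough that sampling error does not
confound the recovery check) — sizes chosen so the complete suite reruns from
scratch in well under half an hour on one CPU while keeping Monte-Carlo
error small relative to the margins being checked.
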