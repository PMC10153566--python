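# Methods

This note documents the models, the numerical choices, and the design
decisions behind `healthdea`, and states what the synthetic-data tests do
and do not establish about real panels.

## Panel model and validation

A panel is a balanced grid of `n` DMUs × `T` consecutive integer periods
with role-tagged measure columns (inputs, outputs, covariates).  Inputs and
outputs must be strictly positive because the SBM objective divides by
them; covariates are unconstrained.  Balance is enforced and missing data
are rejected outright rather than imputed — in this literature incomplete
units are dropped before analysis, and the package requires the caller to
make that decision explicitly.  Consecutive periods are required because
the Malmquist index pairs adjacent periods.  CSV serialisation uses
shortest-round-trip float formatting and round-trip parsing, so
`read(write(p))` is exact; display rounding (3-decimal scores, 2-decimal
percentages) happens only in rendered tables.

## SBM and super-efficiency SBM

The non-oriented SBM is used because orienting the measure to inputs or
outputs alone biases the slack accounting; returns to scale default to
variable (`Σλ = 1`), the standard assumption for administrative units that
cannot be scaled freely, with CRS available by flag.

Both fractional programs are linearised by the Charnes–Cooper
transformation: all variables are scaled by `t > 0`, the denominator is
pinned to 1, and the LP is solved with `scipy.optimize.linprog`
(HiGHS).  De-scaled slacks, reference weights and projection points are
returned alongside the score.  Numerical conventions: a DMU is routed to
the super-efficiency model when `ρ ≥ 1 − 1e-6`; feasibility identities at
the optimum are checked in tests at `1e-7`; degenerate multiple optima are
accepted (any optimal `λ`), since only the optimal value propagates.

One modelling point deserves emphasis.  A literal reading of the
super-efficiency objective as a ratio of bare slack means is degenerate
(an efficient unit has all-zero slacks, giving 0/0), so the package
implements the standard projection-ratio form: minimise the mean relative
input expansion over the mean relative output contraction of a projection
point that the *other* units can weakly dominate.  This is the model that
the widely used DEA solvers implement under the name "super-SBM,
non-oriented".  Under that program, `δ ≥ 1` always, and with at least two
units of positive data the VRS program is always feasible (any single
other unit yields a feasible projection `x̄ = max(x_k, x_b)`,
`ȳ = min(y_k, y_b) > 0`); the oriented variants, not implemented here, are
the ones with a genuine VRS feasibility gap.  Infeasibility is nonetheless
reported honestly as a status, and the combined-score policy for an
infeasible cell is flag-and-omit (clamping to 1.0 is available).

The combined score per DMU-period — `ρ` below the frontier, `δ` on it — is
the quantity tabulated in the score matrix (arithmetic Mean row and
column) and used as the Tobit dependent variable.

### Slack projections

For each sub-frontier DMU the optimal SBM slacks are reported as input
redundancy and output shortage, in measure units and as percentages of the
observed values (`slack / observed × 100`).  Input percentages are strictly
below 100 because a slack equal to the observed input would require a
reference point at zero input, excluded by positivity.

## Radial distances and the Malmquist index

Radial LPs provide Farrell efficiencies (input contraction `θ`, output
expansion `1/φ`), with the Shephard reciprocal convention fixed in the
result type so cross-period ratios are orientation-consistent.  The index
uses the standard decomposition: within- and cross-period CRS distances
for EFFCH and TECHCH, within-period VRS distances for PECH, SECH as the
residual EFFCH/PECH.  Consequently `TFPCH = EFFCH×TECHCH` and
`EFFCH = PECH×SECH` hold to 1e-12 per record (they are built from the same
six LP values), and only the cross-period *CRS* programs — always feasible
for positive data — are ever needed; cross-period VRS programs can be
infeasible and simply report status.

Orientation defaults to output (health services are the maximand) and is
configurable; under CRS the TFPCH/TECHCH components are
orientation-robust.  Summaries are geometric means, the convention of the
DEAP software: on the packaged published index table the printed Mean row
is reproduced by geometric (TFPCH 0.950) but not arithmetic (0.951)
averaging, which settles the convention empirically.  On balanced record
sets the grand geometric mean equals the geometric mean of the per-pair
means (asserted to 1e-12), so the identities survive averaging.
Printed-table identity checks use a tolerance of 1.5e-3: each printed
factor carries ±5e-4 rounding, which propagates to ≈1.5e-3 on a product
compared against a third rounded value (the worst published row,
PECH×SECH = 1.01907 vs printed EFFCH 1.020, sits at 9.3e-4).

## Tobit second stage

The dependent variable — the combined super-efficiency score — is bounded
and piles up near the frontier, so the second stage uses censored-normal
maximum likelihood rather than OLS.  Because super-efficiency scores
exceed 1, the classic censor-at-1 scheme cannot describe them; the default
is left-censoring at 0 (the weakest faithful reading, rarely binding in
practice) with both limits configurable.  With no limits the likelihood is
exactly Gaussian regression, and the fit reproduces OLS coefficients to
1e-6 and the n-denominator ML variance — the closed-form cross-check used
in tests.

Optimisation: BFGS on `(β, log σ)` with the analytic gradient, OLS start,
gradient tolerance 1e-8 (a final gradient norm below 1e-6 counts as
converged when the line search stalls on precision).  Standard errors come
from the inverse observed information — a numerical Hessian in the
`(β, σ)` parametrisation at the optimum — with normal-reference T-ratios
and confidence intervals (level 0.95 by default), and an LR χ² against the
intercept-only Tobit.  Estimates remain finite and convergent up to ~90%
censoring (stress-tested).  Covariate standardisation is exposed as an
option; it is a pure reparametrisation (verified to 1e-6) that improves
conditioning when covariates live on yearbook scales.

Pooling all city-years treats rows as independent, ignoring within-city
correlation; with covariates nearly constant within city the effective
sample for the covariate effects is closer to the number of cities than to
`n × T`.  The package exposes the pooled estimator (the convention in this
literature) and leaves panel-robust variants out of scope.

## Synthetic-data generator

The generator produces the study-shaped world: 19 DMUs × 9 years, three
inputs, two outputs, five covariates.  Defaults were fixed once from the
published descriptive statistics: input base levels equal the first-year
cross-city means; per-input growth factors (1.071, 1.089, 1.171 per year)
reproduce the observed 8-year growth; cross-DMU dispersion is log-normal
with log-sd 0.9 (coefficient of variation ≈ 1.1, matching the heavy right
skew of city sizes), implemented as a common size factor per DMU plus
small per-input jitter, with the log-normal mean correction so the base
levels are means, not medians.  A calibration test checks the final-year
means land within ±50% of the emulated yearbook means — a smoke test of
scale, not a claim of distributional fidelity.

The frontier is Cobb-Douglas with exponents summing to 1 by default, split
across outputs by fixed shares.  With `Σα = 1` the production set is a
convex cone containing the DEA hull, so a unit placed on the surface
cannot be dominated by any λ-combination of units on or below it: frontier
flags in the ground truth are therefore a guarantee, and the pipeline test
asserts every flagged unit scores `≥ 1 − 1e-6`.  A side effect of the
fixed share split is that realized outputs are proportional across output
dimensions, so SBM output-shortage percentages coincide across outputs on
generated panels; real panels do not have this feature.

Technology is Hicks-neutral, `A_t = A_0 g^t` with `g = 0.95` by default,
mirroring the technical regress the motivating study measured.  When input
growth is uniform across inputs and inefficiency is static (noise sd 0),
every DMU's TECHCH equals `g` exactly under CRS with `Σα = 1` — the
parameter-recovery test asserts this to 1e-6.  With the default per-input
growth rates the frontier shift is no longer exactly Hicks-neutral in
measured terms, so recovery is only approximate there; the recovery test
uses the uniform-growth configuration deliberately.

Inefficiency is `u = softplus(γ·z + offset + noise)` for non-frontier
units (u = 0 on the frontier) and outputs are `frontier × exp(−u)`.  The
offset (−1.0 by default) centres softplus in its soft region, giving mean
efficiency ≈ 0.73 among inefficient units — the range of the published
sub-frontier scores; without it softplus(0) ≈ 0.69 would push mean
efficiency near 0.5.  The softplus link is deliberately *not* the Tobit
data model, so γ recovery from scores is approximate by design; exact
Tobit recovery is tested on `generate_tobit_data`, a latent-Gaussian
generator with hard clipping.

The one-period shock multiplies the first output by
`shock_factor^{e_i}` with per-DMU exposures `e_i ~ U(0, 2)`.  The
heterogeneity is essential, not decorative: per-period efficiency scores
are invariant to rescaling an output column uniformly across all DMUs (a
unit change), so a homogeneous shock would be invisible to the score
matrix.  Uneven exposure — the realistic footprint of a natural disaster —
widens the inefficiency spread and depresses the shock-year mean score,
which the tests assert is the panel minimum.

Randomness: one root seed, five named substreams spawned in a fixed
order (sizes, input jitter, covariates, inefficiency noise, shock
exposure), so adding a component never silently shifts existing draws and
equal seeds give byte-identical panels.

### What the synthetic tests do not show

The generator has a single smooth frontier, static covariate mixes, and no
measurement error, spatial structure, or within-city shocks.  Passing its
tests establishes that the solvers and estimators are correct under the
model that generated the data, not that the model describes any real
province; conclusions about real panels still rest on the usual DEA
caveats (deterministic frontier, no noise separation).

## Verification strategy

Three independent routes check the solvers: (i) analytic toys with
closed-form solutions (1-input/1-output sections, the doubling-frontier
Malmquist panel); (ii) a brute-force oracle that grids `λ` over the
simplex at resolution 1e-3 and minimises the SBM objective with slacks in
closed form, agreeing with the LP within 2e-3 on 200 random small
instances; (iii) invariance and identity properties (unit invariance to
1e-7, decomposition identities to 1e-12, monotonicity of ρ in inputs,
OLS equivalence of the uncensored Tobit).  The published score and index
tables are transcribed as fixtures and their printed summary rows are
*recomputed* from the cells, never asserted as constants against
themselves.  One documented transcription quirk: the source text names a
different lowest-scoring city for 2018 than its own table shows; the
fixtures keep the table values.

## Problem sizes

Default test and acceptance runs use panels up to 19×9 (the study shape)
for scoring, 8–12 DMUs over 2–4 periods for Malmquist and pipeline
property tests, 200 random instances for the oracle comparison, and 200
replicates of n = 500 for the Tobit recovery study — sizes chosen so the
whole verification suite completes in well under a minute of LP time while
keeping Monte-Carlo error small relative to the tolerances tested.
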