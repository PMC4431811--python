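# Methods

## Motility parameters

A track is an ordered sequence of 3D positions (μm) at strictly increasing
times (s).  A track with T positions yields T−1 steps.  Per step:

* **instantaneous speed** = ‖p<sub>t+1</sub> − p<sub>t</sub>‖ / Δt × 60, in
  μm/min.  Δt is each step's own frame interval, so variable acquisition
  intervals (e.g. 15–20 s z-stacks) are handled per step.
* **turning angle** = arccos( v₁·v₂ / ‖v₁‖‖v₂‖ ) between consecutive step
  vectors, in degrees; 0° is straight-ahead motion.  The first step of a
  track has no angle.  Steps adjacent to a zero-length step get a *missing*
  angle rather than 0°: arccos is undefined there and imputing 0 would bias
  toward straightness.  Missing angles are excluded listwise from angle
  analyses only.

Cell-based parameters are per-track means and medians of these step
quantities, one row per cell.

**Track filters** (applied before any statistics): fewer than 3 time steps
(< 4 positions); total path length (sum of step displacements) below 17 μm
(≈ 3 cell diameters); squared net start-to-end displacement below 300 μm²
(= 17 μm × 17 μm).  Thresholds and per-rule enable flags are configurable,
since not every dataset is collected with the same non-motile-cell cutoff.
A track can fail several rules; it is counted once per rule and removed
once.  Note the path-length rule implies the displacement rule can also fire
(displacement ≤ path length), so attribution counts overlap by construction.

## Hierarchy and unique IDs

Raw labels (mouse "m1", node "LN1") are only unique within their parent
unit.  Globally unique IDs are built by joining the ancestor labels with a
separator that is backslash-escaped inside labels, making the mapping
injective for arbitrary labels.  A level is reported *aliased* when it is in
one-to-one correspondence with its child level (equal distinct counts under
nesting, e.g. one mouse per date); its variance is then inseparable from the
child's, and nested fits drop it (default, always logged).

## The analysis ladder

All fixed factors use sum-to-zero coding, so each factor's effects sum to
zero and single signed offsets per level are directly reportable.
Per-population estimates are population marginal means — equal-weight
averages over dye levels — which under sum-to-zero coding equal μ̂ + α̂ᵢ and
are invariant to dye relabelling.

1. **t-test**: pooled-variance two-sample t-test; estimates are group means.
2. **Mann–Whitney U**: estimates are group medians.  For samples of ≤ 25
   per group without ties the p-value is the exact U distribution; larger or
   tied samples use the Conover–Iman route (pooled t-test on joint average
   ranks), which tracks the tie-corrected normal approximation closely for
   n ≥ 20.  Plain medians (not Hodges–Lehmann shifts) are reported.
3. **Factorial ANOVA**: population + dye + population×dye by OLS; the
   population p-value is a Wald (type-III-style) test of the population
   block given the other terms.
4. **Mixed-model ANOVA**: adds a per-cell random intercept.
5. **Nested ANOVA**: random intercepts for date, mouse(date),
   node(mouse), field(node), cell(field), honouring the block structure.

Rungs 3–5 have rank-transformed variants: the response is replaced by its
average ranks over the full pooled analysis sample (pooled, not
per-experiment, following the rank-transformation approach as a general
recipe), the same model is fit, and estimates are mapped back to response
units via the inverse empirical quantile function of the pooled response
(linear interpolation between order statistics).  In the two-group
no-covariate case the rank-scale group estimate is the group mean rank,
whose back-map is close to — though not in general exactly — the group
median; back-mapped effects are therefore only approximately sum-to-zero,
while effects on the fitted (rank) scale are exact.  No multiple-testing
correction is applied anywhere; each analysis reports its raw p-value.

## REML engine

Random-intercept models y = Xβ + Σ<sub>l</sub> Z<sub>l</sub>u<sub>l</sub> + e
are fit by restricted maximum likelihood, profiling β and σ² and optimising
the variance ratios λ<sub>l</sub> = σ<sub>l</sub>²/σ² on [0, ∞).  All linear
algebra runs in the q-dimensional random-effect space via the Woodbury
identity (cost independent of n per iteration).  Optimisation is L-BFGS-B
followed by coordinate Brent polish (xatol 1e-11), which reaches the
closed-form answers of balanced designs to ≈ 1e-7 and lands boundary
solutions exactly at λ = 0.  Negative variance components are thereby
truncated at zero and flagged as boundary estimates.  REML (not ML) is used
because it is the standard unbiased-flavoured estimator for variance
components in unbalanced designs.

Denominator degrees of freedom for the population test use the
**Satterthwaite** approximation by default (configurable to residual df):
df = 2f²/(gᵀAg) with f = cᵀCov(β̂)c, g its finite-difference gradient in the
variance parameters, and A twice the inverse finite-difference Hessian of
the −2·REML log-likelihood.  Components estimated on the zero boundary are
held fixed during differentiation.  On balanced one-way designs this
reproduces the classical K−1 between-cell df.  Multi-level (> 2 population)
factors fall back to Wald F with residual df.

Identifiability is checked up front (rank of the fixed-effects design): a
dye observed in only one population makes the interaction unidentifiable
and raises an explicit error.  Models with a single dye level drop the dye
terms with a logged notice so the ladder still runs.

## Simulator

The generator emulates the *structure* of a two-photon experiment, not the
microscope.  Defaults are chosen to resemble lymph-node T-cell data:

* **hierarchy**: totals per level with round-robin child allocation, so
  shapes like 6 mice over 5 dates are honoured exactly; presets mirror the
  four study designs (e.g. 5 dates / 6 mice / 7 nodes / 9 fields).
* **speed**: cell mean speed is log-normal,
  log s = baseline + population + dye + interaction + Σ level effects,
  with baseline log(8) μm/min and per-level normal effects (speeds are
  nonnegative and right-skewed; effects compose additively on the log
  scale).  Per-step speeds are s·exp(σ<sub>e</sub>z), z ~ N(0,1) — note the
  resulting mean step speed is s·e^{σe²/2}.
* **fixed effects** are sum-to-zero: populations[0]/dyes[0] get +effect,
  the other level −effect, so a factorial fit of log speed estimates the
  configured coefficients directly (up to the sign flip induced by
  alphabetical level ordering in the fit).
* **motion**: persistent random walk; each step direction is drawn around
  the previous heading with von-Mises–Fisher concentration κ (κ = 0 ⇒
  uniform directions, mean turning angle 90°; large κ ⇒ straight paths).
  Frame interval 20 s; imaging box 300×300×50 μm by default.
* **censoring**: with `censor_on_exit`, a track ends when the cell leaves
  the box (no re-entry).  Fast cells exit sooner, so step-pooled data
  over-represent slow cells — the sampling bias the mixed models correct.
  Track durations are then naturally unequal, exercising the
  unbalanced-sample-size behaviour of the ladder.
* **dye assignment** is Bernoulli per cell with per-population weights
  (0.5/0.5 = balanced); unbalanced weights plus opposing interaction
  effects reproduce the situation where the naive pooled comparison
  reverses the true population-effect sign.

What the simulator does **not** model: photobleaching/phototoxicity,
cell–cell interactions, tissue structure, drift, tracking errors, or any
biological mechanism of dye effects (they are pure additive offsets).
Passing validation on this generator demonstrates the statistical
properties of the ladder under the assumed dependence structure; it does
not certify behaviour under tracking artifacts or non-log-normal speed
distributions.

## Validation studies and problem sizes

The Monte-Carlo studies in `tracknest.validation` use desk-scale designs
chosen so the effect under study dominates Monte-Carlo noise:

* **type-I calibration**: null population effect, 40 cells/arm × 50 steps,
  σ_cell = σ_step = 0.35 (a realistic cell-to-cell spread producing Fig-2
  style right-skew); the mixed model should reject at ≈ 5% while the pooled
  t-test (design effect ≈ 1 + 49·0.5) rejects an order of magnitude more
  often.
* **coverage**: independent steps (σ_cell = 0) with injected dye (0.10) and
  interaction (0.08) log-speed offsets; OLS intervals on log speed are then
  exactly nominal.
* **censoring**: baseline log(10) μm/min, σ_cell = 0.4, κ = 5, 150×150×50 μm
  box — strong censoring, so the pooled-mean bias (~1.4 μm/min) exceeds the
  ~0.5 μm/min sampling noise of the cell-level mean at 40 cells/arm.
* **confound reversal**: true KO advantage +0.075 on log speed, dye effect
  −0.25, interaction −0.15, 80%/20% unbalanced dye assignment — the pooled
  comparison's expected sign is then wrong by construction while the
  factorial estimand keeps the true sign.

Known limitations: Satterthwaite df are contrast-wise only (no
Kenward–Roger, no multi-df Satterthwaite F); random effects must be nested
(no crossed designs); the rank back-mapping is exact only up to the
empirical quantile interpolation; and numeric agreement with any particular
commercial mixed-model implementation is not guaranteed, since denominator
df conventions differ between packages.
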