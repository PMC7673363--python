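# Methods

This note documents the models and estimators the package implements, the
choices made where more than one convention exists, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Respirometry and SMR estimation

Intermittent-flow respirometry alternates *flush* phases (chamber
re-oxygenated) with *closed* phases in which dissolved O₂ declines at a rate
set by the animal plus bacterial background.  The cycle plan defaults —
120 s flush + 360 s closed (8-min period), 2 s sampling, the first 60 s after
closure discarded, 16 h total — correspond to a standard overnight protocol
for small fish; all are configurable.  Segmentation keeps only complete
cycles: a trailing partial cycle is dropped, never extrapolated.

Each retained window is fitted by ordinary least squares (O₂ vs time); the
slope is reported per hour with its r².  Conventions for degenerate inputs:
a zero-variance (constant) window has slope exactly 0 and r² defined as 0;
windows with fewer than three retained samples are errors.  No r² filtering
is applied by default — an optional threshold exists but exclusion by fit
quality changes the uptake distribution the quantile estimator sees, so it is
off unless requested.

Background correction assumes bacterial respiration grows linearly in time
between a pre-trial and a post-trial blank slope, evaluated at each cycle's
window midpoint (no extrapolation outside the trial).  With a single blank
the background is held constant at that value, with a warning.  Corrected
uptake is `(|b_fish| − |b_blank|) · V_eff` with `V_eff = chamber + tubing −
fish volume` (mL → L); fish volume defaults to mass at tissue density
1.0 g mL⁻¹.  Cycles where the blank exceeds the fish slope produce negative
uptake values; these are *retained* (and logged) rather than clamped, so the
quantile estimator operates on the raw distribution.  A clamp-at-zero option
exists.  Each cycle also records the background share |b_blank|/|b_fish|,
whose trial mean ×100 is reported as the background percentage.

**SMR** is the 0.2-quantile of per-cycle uptake under sorted-order linear
interpolation (plotting position (k−1)/(n−1), numpy's default "linear"
method) — the dominant convention for "lowest 20th percentile" estimators.
The alternative reading (mean of the lowest 20 % of values) is available as
`method="mean_lowest"`, and the descriptor of whichever method ran is stored
in the output.  At least 5 cycles are required (configurable).

A caveat the test suite documents explicitly: *the 0.2-quantile is not
bounded above by the mean for arbitrary inputs* (a left-skewed series of
near-identical values is a counter-example).  In the respirometry regime —
a quiet baseline plus symmetric measurement noise plus strictly non-negative
activity bursts — SMR ≤ mean does hold, and the property tests check it
there; the estimator itself is never clamped toward the mean.

## Air-breathing synchrony

Breath events are counted in half-open bins [k·w, (k+1)·w) with w = 5 s over
the 12-min trial, binned from trial start (t = 0); an event stamped exactly
at the trial end is folded into the last bin so boundary events never vanish.
Short bins keep one fish's surfacing bout from being counted twice.

The coefficient of dispersion is CD = s²/x̄ with the *sample* variance
(n−1); the population-variance alternative is a switch (difference ≤ 1 % at
144 bins).  CD > 1 (strict) flags temporal clustering.  CD is undefined at
zero events: such trials are recorded as missing, not CD = 0, and excluded
from the CD model.  A diagnostic CD with bins offset by w/2 is reported
alongside the primary value as a bin-phase robustness check; it never
replaces the primary statistic.

## Kinematics

Speed: per fish, the mean over consecutive valid frame pairs of displacement
× frame rate; the group value is the **unweighted mean of per-fish means**,
which is robust to unequal valid-frame counts across fish (pooled-frame
averaging is a documented switch).  Cohesion: per frame, the mean Euclidean
distance over all unordered pairs with both members tracked (not
distance-to-centroid); the trial value is the mean over frames with ≥ 2
valid fish.  Missing positions are skipped and the averages renormalised —
never silently interpolated.  An optional centred moving-average smoother
exists because raw tracking jitter inflates speed; it is off by default and
logged when used.  Frame rate and pixel calibration are required inputs with
no defaults, since they are properties of the recording rig.

## Mixed-model battery

The design is repeated-measures: fish nested in groups, each group measured
at two acclimation temperatures (25/30 °C, categorical) and three ambient
oxygen saturations (100/60/20 %, categorical).  The battery:

| response | family | fixed effects | random |
|---|---|---|---|
| log SMR | Gaussian | log mass + temp | fish in group |
| group breaths | neg. binomial | temp + O₂ + speed + cohesion | group |
| CD | Gaussian | temp + O₂ + speed + cohesion | group |
| individual breaths | neg. binomial (Poisson switch) | log mass + log SMR + O₂ × temp | fish in group |
| speed | Gaussian | cohesion + temp × O₂ | group |
| cohesion | Gaussian | speed + temp × O₂ | group |

Gaussian models use statsmodels `MixedLM`; nesting enters as a variance
component on the group:individual interaction.  All selection fits are ML
(REML is a switch for final Gaussian fits, default off, so that
likelihood-ratio tests between fixed-effect structures stay valid).  A small
optimiser ensemble (lbfgs, bfgs, powell; best finite likelihood wins) guards
against under-convergence at the zero-variance boundary, where single
gradient methods stall — without it, occasional nested fits invert the
likelihood ordering.

Count models are fitted by an in-house **Laplace-approximate ML
negative-binomial (NB2) GLMM** with log link and one or more random-intercept
factors: penalised IRLS finds the joint mode of (β, u) at candidate variance
parameters; the marginal log-likelihood is the penalised log-likelihood at
the mode minus ½ log det(I + D Z′WZ); Nelder-Mead handles the outer (log σ²,
log θ) problem, which is derivative-free and robust at σ → 0.  θ is bounded
at 10⁴ — beyond that the NB likelihood is Poisson to ~10⁻⁴ but the
gammaln(y+θ) − gammaln(θ) difference starts losing precision
catastrophically, which an unbounded optimiser will exploit.  Fixed-effect
covariances come from the β block of the inverse joint working Hessian,
conditional on the variance parameters (the glmer convention); adaptive
quadrature is out of scope.  With no random factors the same machinery is
exact ML and matches statsmodels' independent NB regression to 1e-4; with
random intercepts it matches R glmmTMB (nbinom2) to ~0.02 on coefficients
and ~0.05 on the log-likelihood on the test fixture.

**LRT selection** is backward elimination at α = 0.05: at each step every
droppable term is tested (statistic 2·ΔlogLik against χ² with the
parameter-count difference), and the term with the largest p-value above α is
removed; ties in the drop order are thereby resolved largest-p-first.  Terms
are not droppable while they appear in a retained higher-order interaction
(marginality), and log mass is never dropped while log SMR remains, so
metabolic effects are always read conditional on allometric scaling.  A
negative statistic beyond −10⁻⁶ is an error (non-nested or non-converged
models), not silently truncated.

**R²** follows the Nakagawa–Schielzeth variance decomposition: r²m =
var(fixed predictor) / (var fixed + Σ var random + var residual), r²c adds
the random variance to the numerator.  For count families the
observation-level variance on the latent log scale uses the log-normal
approximation ln(1 + 1/λ + 1/θ), with λ the expected count at the mean
linear predictor (exp(mean η_fixed + ½ Σ var random)); the trigamma variant
ψ₁((1/λ + 1/θ)⁻¹) is a switch.  Residual diagnostics are saved as plots
(fitted-vs-residual and normal QQ), not used as an automated gate.

## Synthetic data

The generators encode the statistical structure the analysis assumes, with
every parameter stored as ground truth.

*Respirometry traces.*  Closed phases decline linearly at (uptake/V_eff +
|background|), with the background evaluated at the same window midpoint the
analysis uses, so noiseless round trips are exact to numerical precision.
Flush phases relax exponentially to saturation with a time constant giving
≥ 99 % recovery per flush; only closed phases are analysed, so the flush
shape is immaterial.  Per-cycle uptake is a constant baseline (the true SMR)
plus exponential activity bursts in ~50 % of cycles; Gaussian measurement
noise is added on top.  "1 % noise" means a noise SD of 1 % of the
saturation concentration (0.08 mg L⁻¹ at 8 mg L⁻¹).

*Breath events.*  A common-trigger (batch-arrival) process: each fish has an
independent Poisson stream at rate r(1−p), and group triggers arrive at rate
r with each fish joining each trigger independently with probability p,
surfacing within a 2-s jitter window.  The trigger rate equals the per-fish
base rate by construction, so the expected per-fish total is invariant to p:
p moves only the timing structure (and hence CD), not the totals.  CD
averages ≈ 1 at p = 0 and rises monotonically with p.  Batch arrival was
chosen because the dispersion statistic responds directly to batch size;
self-exciting (Hawkes-type) processes would also cluster events but are out
of scope.

*Trajectories.*  A persistent random walk in a circular arena (3117 cm² by
default): each frame the step direction is the normalised blend of the
previous heading (weight 0.5), isotropic Gaussian noise, and an attraction
component of weight κ toward the current group centroid; the step length is
fixed, and positions crossing the wall are reflected radially inside it.
Putting the attraction *inside* the direction blend (steering) rather than
adding it as a displacement is deliberate: an additive fixed-magnitude pull
makes fish overshoot the centroid once κ exceeds the equilibrium spread, so
group spread is no longer monotone in κ (measured cohesion at step 0.12 cm:
26.6, 0.69, 0.59, 0.84, 1.53 cm over κ = 0, 0.2, 0.5, 1, 2), whereas
steering gives a strictly decreasing 25.1, 5.5, 2.4, 1.4, 1.0 and keeps the
measured speed exact at every κ.  At κ = 0 the stationary distribution is
near-uniform on the disc: measured cohesion at 10⁴ frames is within ~2 % of
the uniform-disc mean pairwise distance 128R/45π.

*Study-level generation* happens at two levels.  `simulate_tidy_dataset`
draws the tidy modelling tables directly: masses log-normal (mean 1.651 g,
CV 0.2), SMR = 0.15·mass^0.89·1.5^[30 °C]·e^N(0,0.1) (mg O₂ h⁻¹), breath
counts from the event simulator at rate 0.5 min⁻¹ fish⁻¹ scaled by O₂
multipliers (1, 1, 1.45 at 100/60/20 %) and a ×1.2 warm-acclimation factor,
p = 0.15 participation.  These effect sizes are synthetic defaults chosen to
mirror the directional biology (more breaths in severe hypoxia, higher SMR
when warm, weak individual-level temperature effect); they are not estimates
from any real dataset.  `simulate_study` additionally renders the raw
streams (traces, events, trajectories) and *recomputes* the tidy tables from
those streams, so the sidecar is exactly what the pipeline should measure;
per-trial step length and attraction vary around their bases so speed and
cohesion are informative covariates rather than constants.  Parameter-recovery
simulations use the tidy level: repeating 16-h signal synthesis hundreds of
times would only re-exercise signal processing that the end-to-end round-trip
tests already cover at reduced durations.

What the generators do **not** emulate: sensor drift and step artefacts in
O₂ traces, identity-swap errors in tracking, observer error in event coding,
diel activity rhythms, and any behavioural feedback between oxygen level and
movement (O₂ level affects only the breath rate).  Passing tests therefore
demonstrate correctness of the estimators under the assumed data-generating
process, not robustness to every artefact of real recordings.

## Problem sizes and reproducibility

Confidence-interval coverage is assessed over 200 replicates of the full
factorial design (6 groups × 7 fish × 2 temperatures × 3 O₂ levels) in the
test suite and 100 in the acceptance script; LRT null calibration uses
500 and 300 replicates respectively; CD calibration uses 1000 twelve-minute
trials; end-to-end pipeline checks run a 2-group, 1-h-respirometry,
150–200-frame study, sizes chosen to keep the full verification cycle at
desk scale.  All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical CSVs, and the run manifest (inputs with
checksums, all effective parameters, package version, seed) suffices to
reproduce a run bit-for-bit.

## Known limitations

- The NB GLMM uses a first-order Laplace approximation; for very small
  counts with many random-effect levels its variance components can be
  mildly biased relative to adaptive quadrature (the usual Laplace caveat).
- `MixedLM` boundary fits (variance → 0) rely on the optimiser ensemble;
  statsmodels can emit boundary warnings that are expected and benign there.
- CD is scale-bound to its bin width: 5-s bins are part of the statistic's
  definition here, and comparisons across bin widths are not meaningful.
- The pipeline models trials as exchangeable given the random intercepts; it
  does not model the progressive-hypoxia time order within a session.
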