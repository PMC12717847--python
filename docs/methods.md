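# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and what the tests do and do not establish.

## 1. The analysis chain

**Dive abstraction.** High-resolution (4-s) depth profiles are reduced
to four interior inflection points by greedy broken-stick selection:
starting from the surface endpoints, repeatedly add the sample with the
largest *vertical* deviation from the current piecewise-linear
reconstruction (ties to the earliest sample).  Vertical deviation, not
perpendicular distance, is the standard choice for time-depth series and
admits a trivially correct brute-force oracle.  Note one property that
is often assumed but is false: the per-iteration maximum deviation is
*not* monotonically non-increasing (a zigzag profile 0, −10, +10, 0
increases it), so the tests pin each iteration's choice against the
oracle instead of asserting monotonicity.

**Exclusion rules.** Retained dives satisfy max depth > 15 m, duration
> 5 min, structural validity (no missing values, strictly increasing
point times), all segment rates ≤ 4 m/s, duration ≤ 90 min, max depth
≤ 2,000 m and surface interval ≤ 10 min.  Rules are applied in that
fixed order and each dive is counted once under the first rule it
fails, making the audit report deterministic and permutation-invariant.
Boundary values follow the strict inequalities as printed (exactly 15 m
is removed; exactly 90 min is retained).

**Track estimation.** ARGOS fixes are speed-filtered (iterative removal
of fixes implying > 4 m/s to both neighbours), then fitted per seal with
a continuous-time correlated random walk: per axis, position integrates
an Ornstein–Uhlenbeck velocity with reversion β (1/s) and diffusion σ.
The model is linear-Gaussian with exact inter-fix transition matrices,
so (β, σ) — shared across the two independent axes — are estimated by
maximising the Kalman likelihood (L-BFGS-B on log-parameters, three
restarts, relative tolerance 1e-8), and positions at arbitrary times
come from the Rauch–Tung–Striebel smoother run over the union of fix
and query times.  One-step-ahead standardised innovations and their
lag-1 autocorrelation are exposed as a diagnostic report, not as an
automated model selector.  Extrapolation beyond the fix span is refused
by default; affected records are dropped with a logged count.

**Drift-rate estimation.** Candidates are interior segments (2–4 of 5)
of dives deeper than 100 m (residual lung air biases buoyancy in
shallower water), with duration ≥ 400 s, |vertical rate| ≤ 0.6 m/s, and
— a dive-shape criterion — a *transit-like* (≥ 0.6 m/s) segment
immediately before them: a passive drift begins when the seal stops
swimming after its descent, whereas slow bottom segments that follow
other slow segments are foraging.  The 400-s floor reflects that real
drift segments last many minutes; both thresholds are config keys
(`CandidateCriteria`) so published settings can be matched.

Screening follows the robust-Kalman idea: the drift-rate trajectory is
a random walk (variance q per day), each candidate speed is either
Gaussian around the state (variance r, weight w) or a uniform
contaminant, and Z is the posterior probability of the Gaussian
component.  (q, r, w) are estimated by a bounded-iteration EM whose
E-step uses a responsibility-weighted forward pass plus RTS smoother and
computes Z from the smoothed posterior predictive; the M-step uses the
mean responsibility for w, a median-based (outlier-resistant) residual
variance for r (capped at (0.05 m/s)², a physical bound for speeds read
off minutes-long summarised segments), and a responsibility-weighted
increment variance for q.  The responsibility weighting of q is what
prevents near-trajectory contaminants from inflating the process
variance and dragging the trajectory after them.  Candidates with
Z > 0.5 are retained; seals with fewer than 5 candidates are left
unscreened and excluded with a warning.

Daily drift rate is the unweighted mean of retained speeds per seal-day;
days without segments are missing, never zero.  Windows of
w ∈ {1, 2, 3, 7, 10} days are consecutive non-overlapping blocks
anchored at each seal's first at-sea day; dDR is the difference between
consecutive valid blocks and is missing otherwise.  A centred running
mean sampled at block mid-times is available (`mode="running"`), but
`block` is the default for both dDR and the metric aggregation so the
join between the two is exact by construction.

**Dive metrics.** Descent rate = d₁/t₁ and ascent rate = d₄/(T − t₄),
absolute values.  The dive residual is the OLS residual of duration on
max depth; the surface residual subtracts a tau=0.05 linear quantile
regression envelope of surface interval on duration (a robust "minimum
recovery time").  Both regressions default to pooled-across-seals scope
so residuals are comparable between individuals (`scope="per-seal"` is
available); the depth–duration relation is fitted linearly, the simplest
defensible reading, with the envelope quantile configurable.  Windows
with fewer than 5 dives are dropped and counted.  Window mean positions
are classified shelf/oceanic by bilinear interpolation of the bathymetry
grid against the 1,500 m isobath; exactly 1,500 m counts as oceanic
(strict "shallower than" reading).

**Response model.** For records (one per seal × window):

y = β0 + β1·dDR + f(DR) + a_i + c_i·dDR + e,  e ~ CAR1(φ) within seal.

f uses a cubic B-spline basis of rank 10 with a second-difference
penalty and a sum-to-zero constraint; after reparametrisation its
penalty null space (one linear-in-DR direction) joins the fixed effects
and its 8 penalized directions enter as an iid random-effect block with
variance τ² — so one REML criterion governs smoothing, the per-seal
random intercept/slope (with correlation), and φ.  σ² is profiled out
analytically; the remaining variance ratios are optimised by Nelder–Mead
on transformed scales (log variances, tanh for the random-effect
correlation, logistic for φ).  Fixed effects, BLUPs and the β1 standard
error come from Henderson's mixed-model equations on CAR1-whitened data
(the whitening is a bidiagonal transform, exact for irregular gaps).
Inference on β1 is Wald; flags are "sig" (p < 0.05), "~" (p < 0.10,
marginal) and "ns".  R² is reported as the squared correlation of
conditional fitted values with observations and is labelled
`r2_fitted_obs` because "goodness of fit" has no unique definition for
penalized mixed models.  Sex and habitat enter as stratified fits, not
interactions — separate models per stratum keep the coefficients
directly comparable and avoid the convergence pathologies of a full
interaction model.

In the degenerate limit (no smooth, no random effects, φ = 0) the same
code path reduces exactly to ordinary least squares, which the tests
verify against the closed form to machine precision.

## 2. The synthetic world

The generator's defaults are the study conditions used throughout the
tests: 30 seals × 180 days, ~60 dives/day of which a random 30–110 are
"transmitted", 2–15 ARGOS fixes/day with conventional class SDs
(0.25–8 km), 4-s depth sampling, and 3.5% drift dives.

**Condition.** Drift rate starts at −0.28 ± 0.03 m/s and follows
mean-reverting dynamics: daily change = 0.025·(−0.05 − DR) + prey
anomaly, clipped to [−0.35, +0.10].  The recovery decelerates as the
seal approaches its equilibrium, reproducing the months-long rise toward
neutral buoyancy with most of the gain in the first ~3 months.  The prey
anomaly is a standardised lognormal field smoothed with a Gaussian
kernel (~30 km) and sampled along a correlated-walk track (~45 km/day,
early seaward bias, reflective domain walls so long trips keep crossing
fresh water); it gives day-to-day dDR fluctuations of sd ≈ 0.025 m/s,
the scale at which drift-rate series visibly wiggle.

**Dives.** Each metric on day d is base + γ·dDR_d + A·h(DR_d) + AR1_d +
noise, with γ defaults +2.0 (transit rates), −3000 s (dive residual,
i.e. ~1 min shorter dives per 0.02 m/s of daily gain) and 0 (surface
residual); h is a saturating tanh in DR with peak-to-peak amplitudes
0.4 m/s, 0.4 m/s, 300 s and 15 s — the surface-residual amplitude is
deliberately small, matching its weakly increasing drift over a trip.
Per-seal heterogeneity: dDR slopes scatter with sd 20% of γ and
intercepts shift per metric; the within-seal AR(1) latent has φ =
0.6/day.  Dive geometry realises the metrics exactly (descent rate =
d₁/t₁ etc.), with maximum depth at the descent end or mid-bottom,
widely varying bottom-phase inflection depths (active hunting spans tens
to hundreds of metres vertically), and durations linear in depth.  Drift
dives descend, then drift for 420–680 s at depth-rate −(DR + ε),
ε ~ N(0, 0.01 m/s); a drift that would hit the seafloor ends early
(truthful in speed, possibly too short to be a candidate) — this
matters on the shelf, where sinking seals cannot complete long drifts.

**What the generator does not emulate.** Real ARGOS error is non-
Gaussian and heavy-tailed; real drift-segment contamination includes
behaviours (benthic resting, thermoregulatory rafting) with their own
temporal structure; transmission gaps are burstier than uniform daily
subsampling; geometry is planar rather than geodesic (a local-tangent
lon/lat adapter exists at the I/O boundary only).  Passing recovery
tests therefore demonstrates the *chain's* correctness under its stated
assumptions, not field performance on any particular real deployment.

## 3. Interpreting recovery results

Because dDR is estimated from screened drift segments, the response
models regress on a noisy predictor: β1 is attenuated toward zero by the
classical errors-in-variables factor λ = var(dDR)/(var(dDR) +
var(error)), ≈ 0.6–0.7 at the daily window under default conditions.
Sign recovery, significance pattern and window attenuation are
unaffected, which is why the replicated experiments check those.  The
confidence-interval calibration experiment fits the model with the
*true* windowed predictors, isolating the property being tested —
whether the penalized-mixed-model intervals cover the generative slope
at their nominal rate — from upstream attenuation, which would otherwise
centre the interval on λγ rather than γ.

Window attenuation is emergent, not injected: effects are generated at
the daily scale only, and block averaging of both response and predictor
dilutes the association as w grows, driving |β1| down monotonically —
the Kendall statistic in the attenuation report quantifies this.

## 4. Numerical choices and problem sizes

Replicated experiments use 20 replicates at 30 seals × 180 days (sign,
null-coverage and attenuation checks; all five windows) and 50
replicates at 15 seals × 120 days (CI calibration), sizes at which each
full-chain replicate runs in seconds and the evidence is comfortably
decisive.  Surface-envelope quantile fits subsample to 30,000 dives
(seeded) when tables are larger and predict in full.  The CAR1 whitening
floors time gaps at 1e-6 day; variance parameters are bounded at e^±25
on the ratio scale; φ is capped at 0.999 and a boundary warning is
emitted above 0.985.  The Nelder–Mead budget (220 evaluations, adaptive)
was chosen to make a single fit ~0.5 s at n ≈ 4,000 records; REML
monotonicity holds along the accepted-step path by construction.  All
randomness flows through integer-indexed `numpy` generators: one stream
per seal plus a world stream, so bundles are bit-identical across runs
for a fixed seed, and experiment replicates derive seeds as seed + index.
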