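# Methods

This note documents the models, estimators and numerical choices behind
`bbbflux`, and what the synthetic cohorts do and do not establish.

## The two-compartment clearance model

Each subject carries three latent curves over the observation week
(t in hours since trauma):

* **CSF concentration** C(t) = A·s(t) + events, where s(t) is a
  mono-exponential decay (half-life `csf_decay_halflife_h`), optionally
  multiplied by a short rise term (1 − e^(−t/τ)) when release accumulates
  over the first hours (`csf_rise_tau_h`).  Secondary-release events —
  Poisson-distributed in time with lognormal sizes — add Gaussian bumps of
  a few hours' width, representing secondary insults that release more
  protein.  A is lognormal across subjects (median `csf_amp_med`, CV
  `csf_amp_cv`).
* **Albumin quotient** Q(t) = qa_base + D·shape(t) for disrupted subjects
  (D = 0 otherwise, disruption probability `qa_disrupted_prob` = 0.5).
  The shape is either a monotone exponential decay from trauma (primary
  mechanical disruption) or a delayed rise-and-decay (vasogenic disruption
  developing over `qa_onset_h` + `qa_rise_tau_h`); an immediate component
  can be mixed in (`qa_early_frac`).  In the barrier-mediated profile,
  release events also open the barrier transiently (`qa_event_coupling`,
  bump width `qa_event_width_h` ≈ 6 h — disruption outlasts the release
  transient).
* **Blood concentration** solves dB/dt = k_bbb·Q(t−δ_bbb)·C(t−δ_bbb) +
  k_alt·C(t−δ_alt) − λ_e·B by forward Euler (step `euler_step_h` = 0.5 h;
  delayed terms vanish while the delayed time is negative).  δ_bbb = 12 h
  and δ_alt = 24 h are the transport delays of the barrier and
  barrier-independent routes.

**Elimination versus "effective half-life".**  λ_e is the *true*
first-order serum elimination rate (half-life 2 h in both profiles).  The
slow serum decays reported clinically (~24 h for S100B, 48–72 h for NSE)
are *observed* decays of the serum curve, which in a two-compartment system
are driven by the decaying CSF input, not by elimination; with fast
elimination the model reproduces exactly that: the simulated serum curves
decay on the CSF timescale (48–60 h half-life) while the blood compartment
tracks the delayed input closely enough for the transport delay to be
recoverable by cross-correlation.  Treating the quoted effective half-lives
as elimination constants instead smears the input over days and displaces
the cross-correlation peak far beyond the transport delay.

**Observation model.**  CSF observations are window means of C over the
preceding 6 h (the drainage pool), timestamped at window end.  Blood
observations are point values of B plus a constant physiologic background
(`blood_floor`: 0.03 µg/L S100B-like, 2 µg/L NSE-like) — serum levels never
fall below the healthy extracerebral scale.  CSF albumin is Q(t)·albumin_blood.
All observations carry mean-preserving multiplicative lognormal noise
(CV 18% for the biomarker immunoassays, 5% for the albumin assays, which
are clinically much more precise).  Schedules: biomarkers 6-hourly for two
days then 12-hourly; albumin 12-hourly starting at 24 h (first routine
daily laboratory draw; 36 h in the NSE profile).  Multitrauma subjects can
receive an additive extracranial blood spike decaying to ~0 by 12 h.

**Calibration.**  The study the cohorts emulate constrains the sampling
design, cohort size (16, half disrupted), the qualitative lag structure
(CSF→blood peak at lag 1 for the barrier-mediated protein, lag 2 with a
lag-0 Q_A:blood peak for the barrier-independent one) and the approximate
concentration scales; it cannot identify k_bbb, k_alt or the event
parameters.  Those defaults were calibrated once so that the two profiles
reproduce the qualitative lag structure at realistic concentration scales,
and are labelled non-identifiable.  Two structural choices deserve
emphasis because they are what make the two profiles distinguishable:
in the barrier-mediated profile, events bump C and Q *simultaneously*
(insults both release protein and open the barrier), so the Q_A:blood
correlation carries the same 12-h transport delay as CSF:blood; in the
barrier-independent profile Q is smooth and uncoupled from events, and its
lag-0 co-movement with blood is pure time-confounding — which is also why
the Q_A fixed effect in the regression stays at its nominal type-I rate
there.

**What the generator does not emulate:** assay platform differences and
calibration drift, hemolysis artifacts in NSE, drainage-rate changes,
treatment effects on the barrier, inter-analyte biology (each profile
simulates one biomarker family), and any outcome process.  Passing tests
therefore show that the *statistical machinery* recovers known structure
under the study's design, not that the biological conclusions transfer.

## Data preparation

Multi-rate series are merged per subject by linear interpolation onto a
regular 6-h grid (the finest sampling interval).  Interpolation operates on
original-scale concentrations; log10 is applied afterwards, so the
cross-correlation path (which must use untransformed data) and the model
path branch from one ingested table.  No extrapolation ever: grid cells
outside an analyte's observed span are missing, and every cell carries a
provenance flag (observed / interpolated / missing).  Complete-case
filtering runs *after* interpolation.  Q_A is derived on the grid from the
interpolated albumin series.  Lag bins and the 12-h early-exclusion window
(applied to S100B-family model fits, where extracranial release
contaminates the first hours) are half-open [a, b): a sample at exactly
12 h belongs to lag 1 and survives the exclusion.

## Correlation estimators

* **Repeated-measures correlation**: common-slope ANCOVA via dummy-coded
  least squares; rho = sign(slope)·√(SS_x/(SS_x+SS_err)),
  df = N − k − 1, p from the F test on the slope, CI by Fisher z with
  SE = 1/√(df − 1).  With one subject it degrades to the Pearson
  correlation with df = n − 2.
* **Per-patient cross-correlation**: the classic estimator with
  full-series means/SDs and the number of valid pairs N(ℓ) in the
  denominator; patients contribute a lag only with ≥ 5 paired bins
  (`min_overlap`), and the default window is ±4 lags (±48 h).
* **Pooling**: across-patient mean with a t-interval per lag
  (m − 1 df); a lag is significant when its CI excludes 0.  The
  construction of pooled uncertainty across patients replaces Bartlett
  bands.
* **Peak choice (one-SE rule)**: among lags whose pooled mean lies within
  one standard error of the maximum — statistically indistinguishable from
  it — the shortest delay is reported (smallest |ℓ|, then the positive
  side).  Lagged correlations of slowly decaying series produce broad,
  near-flat peak regions; the plain argmax then wanders over
  indistinguishable lags, whereas the parsimonious choice is stable and
  favours the shortest delay consistent with the data (the same logic as
  the one-SE rule in model selection).  `peak_se_factor=0` restores the
  plain argmax.
* **Attribution**: the chain CSF → barrier → blood explains the observed
  CSF:blood peak lag L_cb when both links are significant at their peaks
  and L_cb = max(L_cq, 0) + L_qb.  Verdicts: `bbb_mediated` when the
  decomposition holds; `not_bbb_mediated` when the observed lag exceeds
  what the chain explains or a link is not significant;
  `indeterminate` when the CSF:blood peak itself is not significant or the
  ordering is incoherent.

## Longitudinal models

Fixed part: intercept, centered time in days, its square, log10 CSF,
log10 Q_A (time scale configurable).  Residual correlation: stationary,
invertible ARMA(p,q) on the grid, R_i built from the theoretical
autocorrelation (for ARMA(1,1), ρ(1) = (1+φθ)(φ+θ)/(1+θ²+2φθ), ρ(k) =
φ·ρ(k−1)).  β and σ² are profiled out: given correlation parameters,
β̂ = (XᵀR⁻¹X)⁻¹XᵀR⁻¹y via per-block Cholesky solves (blocks cached by
grid signature), and the ML/REML log-likelihoods are evaluated in closed
form.  The mixed model adds a random intercept and slope per subject,
Ψ parameterized through an unconstrained Cholesky factor relative to σ²,
so Ψ = 0 is attainable; a fit on that boundary is flagged and the marginal
model recommended (the population-level fits coincide there).

Numerics: stationarity/invertibility through the smooth
partial-autocorrelation transform, Nelder–Mead with an L-BFGS-B polish,
three deterministic starts (white noise, a moderate-correlation start, one
seeded perturbation); non-PD correlation matrices during the search return
a large penalty.  ARMA CIs come from the numeric observed information on
the unconstrained scale with endpoints back-transformed.  AIC =
−2·loglik + 2·(fixed + correlation + variance (+ random) parameters) holds
as an exact identity on every fit.  REML is used for variance/random
structure selection, ML for fixed-effect LRTs.  The default candidate grid
for structure selection is all (p,q) with p,q ∈ {0..4} (25 candidates);
the pipeline default is the four smallest for speed.

Satterthwaite df for a contrast c: df = 2·Var(cᵀβ̂)²/(gᵀAg), with g the
numeric gradient of Var(cᵀβ̂) in the variance parameters (correlation
parameters, Ψ factor, log σ²) and A the pseudo-inverse of the numeric REML
information (pseudo-inverse so that unidentified variance directions drop
out rather than poisoning the matrix); df is capped at the residual
n − rank(X), and the residual df is used, flagged, when the information
matrix is unusable.  The KPSS level-stationarity screen wraps the standard
statistic with Bartlett-window truncation ⌊4(n/100)^¼⌋ and the published
critical values.

## Problem sizes used in verification

Oracle equivalences run at desk scale (tens of observations) except the
ARMA autocorrelation check (10⁷ simulated steps).  Lag-structure recovery
uses 20 replicate cohorts of 16 subjects per profile and requires ≥ 15/20
successes.  Operating characteristics: 20 replicate mixed-model fits for
the Q_A type-I rate and time power; 100 replicates of a 16-subject ×
50-observation GLS design (800 observations, β set to clinically reported
S100B clearance coefficients, φ = 0.637/θ = 0.621) for CI coverage; 100 replicates
each for KPSS size and LRT size.  Parameter recovery uses an 800-subject ×
25-observation design (50× the study size) at φ = 0.976/θ = 0.563.

## Known limitations

* The contemporaneous-covariate regression understates a causal barrier
  term when transfer is delayed: in barrier-mediated cohorts the Q_A
  coefficient at n = 16 is only intermittently significant (the
  cross-correlation analysis is the sharper instrument for delayed
  transfer).  Coefficient signs in such misspecified-lag fits are not
  interpretable as transfer directions.
* The lag attribution composes peak lags; it cannot distinguish a true
  barrier chain from a coincidental additive arrangement of smooth trends,
  and flat pooled curves make the peak (and hence the verdict) sensitive
  to the one-SE threshold.
* Percentages in cohort summaries are rounded half away from zero to one
  decimal per level, so a categorical variable's percentages can sum to
  100 ± 0.05·(number of levels).
* The generator's event mechanism and barrier-trajectory shapes are
  identification devices, not validated physiology; only the sampling
  design, the disruption mixture and the qualitative lag structure are
  anchored to observed data.
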