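# bbbflux

Does a brain-injury biomarker leave the injured brain through the disrupted
blood–brain barrier, or around it?  `bbbflux` is a Python toolkit for
answering that question from longitudinal, multi-compartment monitoring
data: serial CSF and blood concentrations of brain-enriched proteins
(S100B, NSE) sampled every 6–12 h over ~1 week of neurocritical care,
together with CSF and blood albumin sampled once or twice daily.

It is aimed at neurotrauma and biomarker researchers who have (or want to
simulate) high-frequency two-compartment data and need the full analysis
chain: alignment of multi-rate series, repeated-measures correlation,
per-patient lagged cross-correlation with pooled inference, and regression
models with a within-patient ARMA(1,1) error process.

## The quantities and models at the core

**Barrier integrity.** The CSF:blood albumin quotient

&nbsp;&nbsp;&nbsp;&nbsp;Q_A = albumin_CSF / albumin_blood

(dimensionless; CSF albumin in mg/L is converted to g/L first) is the
laboratory gold standard for blood–brain/blood–CSF barrier disruption:
albumin is only made peripherally, so a high quotient means a leaky
barrier.  Age-banded reference bounds (e.g. Q_A < 0.006 below 30 years,
< 0.009 from 50) are built in.

**Momentary association.** The repeated-measures correlation fits the
common-slope ANCOVA y ~ subject + x and reports
rho = sign(b)·√(SS_x/(SS_x+SS_err)) with df = N − k − 1 (N observations,
k subjects), a within-subject correlation immune to between-patient level
differences.

**Delayed association.** Raw (untransformed) series are averaged into
half-open 12-h bins ("lags"); for each patient the lagged correlation

&nbsp;&nbsp;&nbsp;&nbsp;r(ℓ) = Σ_k (x_k − x̄)(y_{k+ℓ} − ȳ) / (N·s_x·s_y)

is computed and pooled across patients with a t-interval per lag.  The peak
lag (chosen parsimoniously: the shortest delay statistically
indistinguishable from the maximum) localizes the CSF→blood transport
delay, and the three pairwise peak lags — CSF:Q_A, Q_A:blood, CSF:blood —
are composed to decide whether the delay is barrier-mediated.

**Inference.** log10 blood level is regressed on time from trauma (days,
centered), time², log10 CSF level and log10 Q_A, with the within-patient
residual following a stationary, invertible ARMA(p,q) on the alignment
grid.  Both a marginal model (generalized least squares, block-diagonal
R_i(φ,θ)) and a linear mixed model (random intercept + random slope in
time, V_i = Z_iΨZ_iᵀ + σ²R_i) are fitted; REML for variance structure, ML
for fixed-effect likelihood-ratio tests, AIC over a grid of (p,q)
candidates, and Satterthwaite effective degrees of freedom for the final
p-values.  A KPSS screen justifies modelling in levels (no differencing).

**Synthetic cohorts.** Because no patient-level data are public, the
package ships a seeded two-compartment generator: CSF release decaying
exponentially (plus secondary-release events), a barrier trajectory Q(t),
and blood appearance through a barrier route k_bbb·Q(t−δ)·C(t−δ) and/or a
delayed barrier-independent route k_alt·C(t−δ′), integrated by forward
Euler and observed on realistic schedules with lognormal assay noise.  Two
profiles encode the competing hypotheses: `s100b_like` (barrier-mediated,
12-h delay) and `nse_like` (barrier-independent, 24-h delay).

## Worked example

```bash
python analysis/01_power_and_cohort.py
python analysis/02_simulate_cohorts.py
python analysis/03_cross_correlations.py
```

prints

```
detecting r = 0.6 at 80% power (one-sided alpha 0.05) requires n = 15 subjects (power at n: 0.798)
cohort of 16: median GCS 7 (IQR 3.75-7.25); lesion progression 5/16 = 31.3%
s100b_like: 1024 measurements, 16 subjects (8 with a disrupted barrier) -> results/cohorts/s100b_like
nse_like: 992 measurements, 16 subjects (10 with a disrupted barrier) -> results/cohorts/nse_like
s100b_like: peak lags CSF->QA 0, QA->blood 1, CSF->blood 1 (1 lag = 12 h) -> verdict bbb_mediated
nse_like: peak lags CSF->QA 0, QA->blood 0, CSF->blood 2 (1 lag = 12 h) -> verdict not_bbb_mediated
```

Reading the output: 15 subjects suffice for the design-stage power target;
the summarized cohort is severe TBI (median admission GCS 7) with CT lesion
progression in 31.3%.  In the barrier-mediated cohort the blood signal
follows CSF by one 12-h lag and Q_A shows the identical one-lag lead on
blood, so the delay is attributed to barrier passage.  In the
barrier-independent cohort blood trails CSF by two lags (24 h) while Q_A
co-moves with blood at lag 0 — the barrier chain cannot account for the
delay, and the verdict is `not_bbb_mediated`.

`analysis/04_clearance_models.py` and `analysis/05_full_runs.py` continue
the chain (ARMA selection, GLS/mixed fits with Satterthwaite p-values, and
the all-in-one pipeline with manifests, lag panels and markdown reports).
The same pipeline is scriptable from the shell:

```bash
bbbflux run --profile s100b --n 16 --seed 1 --out runs/demo
bbbflux power --r 0.60
```

Note that single-cohort coefficient tables at n = 16 are noisy; the
operating characteristics of the fits (type-I rate of the Q_A term, power
of the time term, CI coverage) are established over replicate simulations
in the test suite, not from one run.

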