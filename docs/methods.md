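# Methods

## The kinetic model

The package models two-substrate reductase kinetics with the
substituted-enzyme (ping-pong bi-bi) rate law: the reducing cosubstrate A
(BNAH, NRH, NADH, NADPH) reduces the flavin and leaves before the electron
acceptor B (menadione) binds. Observed velocity:

v = E0·kcat·[A][B] / ( K_A·[B]·(1 + [B]/K_I) + K_B·[A] + [A][B] )

Internal units are µM for concentrations, s⁻¹ for kcat and nM for the
enzyme concentration E0 (converted internally), so velocities are µM·s⁻¹ —
the natural scale of an absorbance-derived rate. The (1 + [B]/K_I) factor
models acceptor substrate inhibition and collapses to 1 when K_I is absent.
Catalytic efficiencies are reported as kcat/K_A in M⁻¹·s⁻¹ (a ×10⁶
conversion applied only at the reporting boundary), the unit in which
quinone-reductase cosubstrate comparisons are conventionally quoted.

The rate-law output is the *observed* velocity E0×(turnover rate): assay
tables print per-assay enzyme concentrations, and initial rates extracted
from absorbance traces are concentration/time, so E0 scaling is part of the
model rather than a post-hoc conversion.

## Initial rates from progress curves

Absorbance traces are converted to concentration by Beer–Lambert,
c = A/(ε·l)×10⁶ µM, with ε (e.g. 6220 M⁻¹cm⁻¹ for NAD(P)H at 340 nm) and a
per-well pathlength supplied as metadata — plate-reader pathlength
correction enters as a measured/nominal input rather than being estimated
from the trace. The initial rate is the OLS slope over the longest prefix
window in which at most a set fraction (default 10%) of the initial
substrate has been consumed and which contains at least 5 readings; the
estimate is minus the slope, so consumption is positive. Degenerate traces
(no variance, window too short) are rejected, not raised. An optional
paired enzyme-free blank on the same time base subtracts background drift.

The linear-window estimator is deliberately simple and carries a known
small-sample bias: for a trace with relative curvature κ = (consumed
fraction over the window), the OLS slope underestimates the initial
derivative by ≈ κ/2 (e.g. ~5% at a 10% consumption window on an
exponential). The tests assert against this closed-form expectation rather
than pretending the estimator is exact; tightening `max_consumed_frac`
trades precision for noise.

## Global fitting and uncertainty

Parameters are estimated by unweighted least squares over all grid points
jointly (replicates enter as independent observations, no pre-averaging).
Optimisation runs in log10-parameter space — positivity holds by
construction and no active bounds arise — from at least 8 starts: kcat
seeded from max(rate)/E0, Michaelis constants log-spaced across the tested
concentration ranges, K_I log-spaced up to 10× the largest tested acceptor
level. The lowest-RSS solution wins; total failure returns a diagnostic
results object rather than raising. On two-parameter problems the optimum
was checked against dense brute-force RSS lattices.

Confidence limits are asymptotic t-intervals from a Jacobian covariance
mapped back to natural units by the chain rule. The default covariance is
the HC3 heteroscedasticity-consistent sandwich rather than the classical
s²(JᵀJ)⁻¹: assay noise is approximately proportional to the rate while the
loss is unweighted, and under that mismatch the classical estimator
materially understates the uncertainty of kcat (simulated coverage ~60% at
nominal 95%), whereas the HC3 sandwich restores near-nominal coverage
(~93% in the recovery simulations). The classical estimator remains
available via `cov_type="homoscedastic"`; 1/Y²-weighted fitting was
deliberately left out of the default path to keep the estimator the plain
unweighted fit practitioners run in Prism-style software.

Substrate-inhibition model selection fits the with- and without-K_I models
and retains K_I only when the extra-sum-of-squares F-test favours it at
α = 0.05 *and* the estimate is identifiable (K_I below 10× the largest
tested acceptor concentration); otherwise the report says ND, matching the
published-table convention. For poor cosubstrates the acceptor constants
are frozen at the values determined with a good cosubstrate and only
(kcat, K_A) are fitted; when the cosubstrate cannot saturate the enzyme at
all, the efficiency-only fallback fits the single slope of the linear
regime v ≈ E0·(kcat/K_A)·[A]/(1 + [B]/K_I) and reports kcat and K_A
individually as ND. The fallback refuses grids whose constrained fit
confidently places K_A inside the tested range (a plateau is present). A
subtlety worth noting: at fixed acceptor concentration the *apparent*
Michaelis constant is K_A·[B]·(1+[B]/K_I)/(K_B+[B]), roughly 2.5-fold
smaller than K_A for the NADH presets, so "linear regime" must be judged
against the apparent constant, not K_A itself.

Reported efficiency is exactly the quotient of reported kcat and K_A; its
CI comes from first-order (delta-method) propagation using the parameter
covariance, including the kcat–K_A covariance term.

## Dose-response analysis

Raw SRB absorbances (560 nm) are normalized per condition by the mean of
that condition's untreated (zero-dose) wells; untreated wells therefore
average exactly 1 and are excluded from the log-concentration fit. The
variable-slope four-parameter logistic is fitted by bounded multi-start
least squares on (top, bottom, log10 IC50, hill). Because normalization
anchors the upper plateau, `top` is fitted only within [0.95, 1.05]
(several multiples of the normalization SE under the default design);
without this anchor, the IC50 of a strongly potentiated curve whose entire
tested range lies above the IC50 — exactly the CB1954+NRH situation — is
unidentified and biased upward. `bottom` is constrained to [0, top); hill
is free.

Parameters that end on an active bound are constrained, not estimated, so
the covariance (and the log10-IC50 standard error) is computed over the
free directions only; including bound-pinned parameters inflates the IC50
standard error by an order of magnitude and makes every comparison
spuriously insignificant. IC50 CIs are t-intervals on the log10 scale,
exponentiated. Fits whose fitted curve never crosses the 0.2–0.8 viability
band are flagged `ic50_unbounded` and excluded from quantitative
comparison.

IC50s are compared on log10 scale (IC50 sampling distributions are
approximately log-symmetric) by a two-tailed Welch t-test with
Satterthwaite degrees of freedom from the two fits' standard errors; a
flagged fit downgrades the comparison to qualitative-only.

## Synthetic data: what it emulates, what it does not

The generator encodes the two study designs as presets with
machine-readable ground truth:

- **Kinetic grids.** Triplicate rates over 8 log-spaced cosubstrate levels
  (BNAH 5–340 µM, NAD(P)H 40 µM–12 mM) × acceptor levels (menadione
  2–100 µM; 6 levels, or 10 for the dense designs used when substrate
  inhibition must be resolved; 20/40 µM fixed pairs for NAD(P)H). Truth
  parameters are the published kinetic constants per species/cosubstrate;
  enzyme concentrations follow the assays (0.46/2.06/4.89 nM for BNAH;
  NAD(P)H assays used µM-level enzyme, encoded as range midpoints). Noise
  is proportional-plus-additive Gaussian, default 5% proportional and no
  additive term, truncated at zero.
- **Progress curves.** Cosubstrate depletion is integrated (RK4 with
  automatic step refinement against a half-step control) at the model rate
  with the acceptor held constant — justified by the short initial-rate
  window — then converted to absorbance and given Gaussian read noise.
  Plate-reader defaults: 91 reads, one per minute.
- **SRB plates.** Per-condition logistic truths; the knockout-experiment
  preset uses a parental CB1954 IC50 of 200 µM dropping 45-fold with NRH
  and an NRH-insensitive knockout. Two-fold dilutions 7.8–1,000 µM,
  triplicate, 6 untreated wells, absorbance scale 1.0 AU with sd 0.04
  (≈4% CV, typical for an SRB readout; the study reports only n = 3).

All generators are pure functions of (scenario, seed). The simulations do
not model FAD spectral interference, instrument drift, plate edge effects,
acceptor depletion, or non-Gaussian outliers — so passing recovery tests
demonstrate estimator correctness and calibration under the stated noise
model, not robustness to every artefact of real plate data.

## Problem sizes and numerical choices

Recovery simulations use 200 replicate experiments for confidence-limit
coverage (binomial sd ≈ 2% at 95% nominal), 100 replicates per arm for
substrate-inhibition selection rates, 50 seeds for dose-response fold
recovery, and 500 plate pairs for the null calibration of the IC50 t-test;
these sizes make the binomial acceptance bands meaningful while keeping
the whole suite fast. Optimiser tolerances are left at scipy defaults for
the kinetic fits (the log-space parameterisation is well conditioned) and
tightened to 1e-14 for the dose-response fit so noise-free round trips are
exact to ≤1e-6. Ties and degenerate inputs resolve conservatively:
constant traces are rejected rather than fitted, all-zero rate grids yield
zero efficiency with an infinite relative CI and a `degenerate` flag, and
fit failures surface as flagged results, not exceptions.

## Known limitations

- The confidence limits are asymptotic; profile-likelihood intervals are
  not implemented, and for parameters near identifiability boundaries
  (K_I with sparse acceptor coverage, K_A without a plateau) the t-interval
  is only a first-order approximation — the selection rules exist
  precisely to flag those regimes as ND.
- The Welch t-test treats the two log10-IC50 estimates as independent
  normals with known-enough variances; with 3 replicates per dose this is
  an approximation, calibrated here to a 3–8% empirical size at α = 5%.
- The efficiency-only fallback assumes the tested range is genuinely
  sub-saturating relative to the *apparent* Michaelis constant; its guard
  is heuristic and can be overridden by supplying no K_B.
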