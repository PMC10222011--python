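# Methods

This note documents the statistical model behind `pfmetallome`: what the
simulator generates, how each validation statistic is defined, the defaults
and why, and what the package's passing tests do and do not establish about
real instrument data.

## The measurement model

A measured channel is a count rate (counts s⁻¹) for one analyte isotope in
one acquisition mode.  The simulator's noiseless expectation for a solution
with in-sample analyte concentration `C`, dilution factor `DF`, and matrix
profile `M` is

    I = S_mode · (C/DF) · f_el(DF) + Σ_t k_t,mode · [source_t] + B

* `S_mode` — channel sensitivity (cps per µg L⁻¹).  He mode multiplies all
  analyte and internal-standard sensitivities by α = 0.5: the collision gas
  scatters analyte ions too, which is why detection limits for clean
  channels are *worse* in He mode.
* `f_el(DF) = 1 + a_el/DF` — the residual matrix effect after
  internal-standard correction.  It tends to 1 with dilution, and the 1:4
  factor is always closer to unity than the 1:2 factor, which is the entire
  case for the 1:4 routine dilution.  Amplitudes `a_el` are ±0.22 for
  elements whose 1:2 recoveries leave the tolerance band and ±0.16 for the
  rest, signed to match the observed direction per element.  Internal
  standards carry no residual effect by construction (the amplitude *is*
  the residual).
* Interference terms `k_t,mode·[source_t]` are additive count rates.
  Matrix-sourced terms (Cl, Ca, C, S, Na precursors) use the diluted
  component concentration and form only in aliquots that also carry the
  acid load of the added multielemental standard; plasma-sourced terms
  (ArO⁺, ArN₂⁺, …) are always present, blanks included.  In He mode each
  term's coefficient is multiplied by its own attenuation (10⁻³–10⁻² for
  collision-correctable polyatomics; ~0.45, i.e. essentially uncorrected,
  for the ⁷⁵As pathway, which is flagged `correctable_by_he = False`).
* `B` — a constant per-channel baseline (400 cps default).

**Why spike-activated matrix interference?**  The spike-recovery statistic
subtracts the unspiked aliquot from the spiked one, so any interference
present identically in both cancels exactly — under a purely additive model
no interference could ever spoil a recovery, contradicting the
gross (≈6000 %) apparent Fe recoveries such assays show in no-gas mode.
Physically, polyatomic formation responds strongly to the co-introduced
acid/carbon load; modelling the matrix-sourced terms as activated by the
added standard reproduces, from one closed form, (i) the ~6000 % no-gas Fe
recovery at a 100 µg L⁻¹ spike, (ii) its repair to ≈95 % in He mode,
(iii) monotonicity of apparent recovery in each interference coefficient,
and (iv) unbiased unspiked/cohort measurements.  Blank-side interference
(and hence the inverted LOD ordering for interfered channels) is carried
entirely by the always-on plasma terms, whose formation is given extra
shot-to-shot instability (CV 0.25) because polyatomic backgrounds are far
less stable than analyte signal.

### Stochastic layers

Each recorded intensity is the expectation times a common per-day drift
factor `1 + 0.02·day` (applied to analyte *and* internal standard, so it
cancels in ratios — the point of internal standardization), times a
lognormal factor with CV 2 %, plus a Poisson-like additive noise of
variance equal to the expected count rate.  Day-level sample preparation
multiplies the analyte signal of all validation aliquots prepared that day
by a shared factor with SD 2 % — this is the variance component the
between-day ANOVA term estimates.  Setting `noise_cv = 0` switches the
whole stochastic layer off, making runs exactly equal to the closed form
(used by the oracle tests).  All randomness derives from `RunDesign.seed`.

### What the simulator does not emulate

No mass-spectral peak shapes, no doubly-charged or isobaric overlaps beyond
the five listed channels, no plasma physics (the As charge-transfer pathway
is a fixed attenuation flag, not a mechanism), no inter-element sensitivity
drift, no carryover/memory effects, and cohort truth values are drawn
uniformly inside observed concentration ranges rather than from a real
population.  Passing tests therefore demonstrate that the *statistics* are
implemented correctly and behave as designed under their own assumptions —
not that the simulator predicts any particular instrument.

## Study design (defaults)

8 calibration levels spanning 0.05–1000 µg L⁻¹ × 5 replicates; 10
consecutive blanks; dilution study at 1:2 and 1:4 on five fluids spiked at
100 µg L⁻¹ (in-sample); validation grid of 5 spiked sub-samples × 4 days at
50 µg L⁻¹ with daily unspiked aliquots and daily aqueous standards; a
20-sample cohort at 1:4; internal standards at 40 µg L⁻¹; both acquisition
modes throughout.  Spike concentrations refer to the undiluted sample; the
aqueous recovery standard is measured neat at `spike/DF` so its signal
matches the added signal seen in the diluted solution (this also reconciles
a "50 ppb" standard with a 100 µg L⁻¹ spike measured at 1:2).  The
validated aliquot's native levels default to 2 µg L⁻¹: a spike-recovery
design at 50 µg L⁻¹ is only statistically meaningful when the native level
does not dwarf the spike.

## Calibration

Replicate ratios are averaged per level; the line is fitted by
inverse-variance weighted least squares with weights from each level's
replicate scatter.  Weighting is load-bearing: with multiplicative noise
over four decades, an unweighted fit hands the intercept several µg L⁻¹ of
top-standard scatter (measured in development: sub-µg L⁻¹ cohort
predictions off by 5–13 µg L⁻¹), which destroys censoring and mode
agreement.  Degenerate (noiseless) levels fall back to the smallest
observed scatter so exact data still fit exactly.  Acceptance requires
weighted R² > 0.995 and a positive slope.  Inverse prediction is
`C = ((y − b)/m)·C_IS·DF`; negative estimates are preserved for the
censoring stage.

## Detection limits

`s_b` is the n−1 standard deviation of blank analyte/IS *ratios* (ratio
units keep LOD = 3·s_b/m·C_IS consistent with the inverse prediction);
LOQ/LOD = 10/3 identically.  Limits are reported in measured-solution
concentration (no dilution rescaling; a config switch applies it).  With
day-labelled blanks, per-day limits are averaged arithmetically.  Blank
ratio SDs that are pure floating-point residue of constant blanks are
snapped to zero and flagged degenerate.

## Recovery and mode choice

Recoveries are computed on internal-standard ratios, with the aqueous
standard blank-corrected by the mean calibration blank.  Daily recovery is
the replicate mean; the interday figure is the mean ± SEM over days;
tolerance is [90, 110] % (configurable).  The dilution comparator counts
elements inside tolerance per factor (no-gas mode, as in the optimization
study) and recommends the factor with more, breaking ties toward the higher
dilution.  Mode agreement compares cohort concentrations between modes only
where both values are quantifiable and the element is free of spectral
interference.

## Uncertainty budget

The validation grid value is the *found added* concentration: predicted
spiked-sub-sample concentration minus the same day's mean unspiked-aliquot
concentration, so native level and any common background cancel.  The
one-way ANOVA reads days as groups; the between-group variance component
is clamped at zero.  The "RSD" symbols of the precision equations are taken
as the ANOVA standard deviations in concentration units (the only reading
that lands u_rep/u_ip at the ~1–3 % scale the budget tables show).
RMS bias uses per-day means with n_days in the denominator.  u_conc and
u_prep are config constants, defaulting to 0.5 % and 1.0 % of the spike
level (0.25 and 0.5 µg L⁻¹ at 50 µg L⁻¹) — the stock-solution certificate
and gravimetric preparation scales typical of such work.  U = k·√(Σu²),
k = 2; budget tables are reported at one decimal.

## Profiling

He mode is routed for Cr, Cu, Fe, Zn; arsenic is excluded with a distinct
status; everything else reports from no-gas mode.  Censoring: conc < LOD →
below-LOD; LOD ≤ conc < LOQ → below-LOQ; conc ≥ LOQ → quantified (boundary
inclusive at LOQ, documented convention); negative estimates → below-LOD.
Detection percentage counts samples at or above LOD; mean/SD/SEM/min/max
are computed over quantified values only, with no imputation — both SD and
SEM are emitted explicitly because "SEM"-labelled spreads in this
literature are frequently SD-sized.

## Numerical and design choices

* Sensitivities, baselines and interference coefficients are free
  instrument-scale parameters (no raw intensities exist to match); they
  were fixed once so that blank-limited limits reproduce the observed
  orderings between modes and the interference-to-signal ratios quoted
  above, and are not tuned thereafter.
* One calibration per element × mode is fitted from the pooled calibration
  stage; day drift cancels in ratios, so day-specific curves would differ
  only by noise.
* Problem sizes in the test suite (200-seed round-trips, 100-grid oracle
  equivalence, 500-grid parameter recovery, the full default study) were
  chosen to keep the whole suite in the ten-second range on one core.
* Ties and degenerate inputs: equal in-tolerance counts → higher dilution;
  s_b = 0 → zero limits with a warning flag; empty cohort → pipeline
  completes through the budget stage with empty profile outputs.

## Known limitations

The interference model is parametric, not mechanistic; its spike-activation
term is a deliberate simplification with the right fixed points rather than
plasma chemistry.  Censored summaries discard below-LOQ information rather
than using maximum-likelihood left-censored estimators.  The weighted
calibration assumes the per-level replicate scatter estimates the true
level variance (5 replicates make these weights noisy, which costs
efficiency, not bias).  Uncertainty budgets propagate neither calibration
covariance nor interference-correction uncertainty.
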