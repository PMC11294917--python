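# Methods

This note documents the models, conventions and numerical choices behind
`prmquant`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and units

Retention time is canonically in **minutes** everywhere; mzML files
recording seconds (or milliseconds) are converted on read. m/z is in
Thomson, intensities in counts (MS1 stick intensities are interpreted as
counts-per-second, cps, the unit the scheduling threshold is defined in).
Concentrations are in ng/mL. Integrated areas are counts·minutes.

Input spectra must be centroided. Profile data is rejected with an explicit
error rather than peak-picked: peak picking is a vendor-/instrument-specific
transformation outside this package's scope, and silently centroiding would
change quantitative results.

mzML is read and written by a self-contained serializer/parser (PSI mzML
1.1.0; 64-bit uncompressed arrays on write; 32/64-bit, zlib or uncompressed
on read; indexed and plain documents). The test suite validates the writer
against an independent reader (Bioconductor `mzR` via Rscript) and by
round-trip: scan counts, MS levels, RTs (≤1e−9 min) and centroid arrays
(≤1e−6 relative) are preserved.

## PRM extraction

1. **Scan matching.** An MS2 scan belongs to an inclusion-list entry when
   |precursor m/z − entry m/z| / entry m/z · 1e6 ≤ tolerance (default
   25 ppm, appropriate for QToF-class accuracy) and |rt − rt_center| ≤
   window/2. The acquisition window (default 1 min full width, i.e.
   rt_center ± 0.5 min) doubles as the integration window unless
   overridden. When two entries match one scan, the scan is assigned
   exclusively to the entry with the smaller ppm distance, ties broken by
   smaller |rt − rt_center|; every scan therefore contributes to at most
   one target per extraction pass.
2. **Fragment selection.** The n most intense fragments (default n = 3 —
   enough for specificity while tolerating weakly fragmenting analytes) are
   taken from the target's reference MS2 spectrum; intensity ties break
   toward lower m/z. Selected fragments are recorded in the output.
3. **Trace extraction.** Per matched scan and per fragment, the intensity is
   the sum of all centroids within the ppm window (zero if none); each
   trace has exactly one point per scan, so all traces of a target share
   one rt grid.
4. **Integration.** The per-fragment traces are summed and
   trapezoid-integrated over the window. By linearity this equals the sum
   of per-fragment trapezoidal areas (the suite checks both routes to
   ≤1e−9 relative). No smoothing, baseline subtraction or peak modelling:
   the window bounds define the integral, which keeps the estimator linear
   in intensity (areas scale exactly with intensity) and free of tuning
   parameters.

Fewer than two scans in a window cannot be integrated; the area is reported
as 0 with a warning (not an error), so batch processing survives dropouts.
DDA MS1 quantitation applies steps 3–4 to the precursor XIC over MS1 scans;
MRM quantitation applies step 4 to the recorded transition trace. All three
modes emit the same area record (target, sample, mode, area, scan count,
fragments used).

## Calibration and figures of merit

The response is the peak-area ratio R = A_analyte / A_IS; a missing or
non-positive internal-standard area is a hard, sample-named error (a real
failure mode when the IS fragments poorly). Calibration minimises
Σ w_i (R_i − m·x_i − b)² with w_i = 1/x_i (or 1), computed by weighted
least squares (statsmodels WLS behind the `CalibrationModel` estimator).
1/x weighting equalises relative influence across the four-decade dynamic
range of the ten-level design (0.5–10 000 ng/mL); zero-concentration points
have undefined weight and are excluded with a warning. Back-calculation is
x̂ = (R − b)/m; sub-blank responses yield negative x̂, which is reported
and flagged, never clipped, so downstream statistics see the raw estimate.

**LOD/LOQ.** LOD = 3·SD and LOQ = 10·SD exactly, with SD the n−1 sample
standard deviation of back-calculated concentrations from replicate
injections of the lowest quantifiable standard. A blank-based SD is not
usable here: blanks have zero nominal concentration, which the 1/x-weighted
fit excludes by construction. Precision is reported as
%CV = 100·SD/mean (n−1 SD).

**Linear range.** The paper-style range report needs an explicit rule; the
package uses the widest contiguous run of calibration levels whose mean
back-calculated accuracy |x̂/x − 1| stays within a tolerance (default 20 %,
a config knob). Levels with uniformly zero response (non-detects, e.g.
below the PRM scheduling threshold) carry no calibration information and
are excluded from fits and merit statistics by the pipeline.

**Glycoside diagnostics.** The glycone/aglycone ratio (intact-glycoside
area over aglycone area) summarises in-source harshness; a
(temperature × voltage) grid maps to a ratio-surface table. The table is a
summary, not an optimiser — choosing operating conditions is left to the
analyst.

## Deming method comparison

With equal error variances assumed in both methods (δ = 1), the fit is
orthogonal least squares with the closed form given in the README; the
positive root shares the sign of s_xy and minimises the perpendicular SSE
(verified against a brute-force grid minimiser to ≤1e−6). δ is exposed for
generality. Degenerate orientations (s_xy = 0) are errors rather than
arbitrary lines. Confidence intervals are 95 % leave-one-out jackknife
(slope and intercept); with n < 4 the jackknife is unstable and intervals
are reported as missing, never fabricated. Agreement is flagged when the
slope CI contains 1; if no CI is available, a documented fallback of
|β − 1| ≤ 0.2 is used. Pairs are dropped (and logged) when either axis is
missing; no log-transformation is applied before regression.

## The acquisition simulator

The simulator emulates the acquisition behaviour the extraction code must
survive, not instrument physics:

- **Chromatography**: Gaussian peaks I(t) = F·c·exp(−(t−t_R)²/2σ²) with
  response factor F (cps per ng/mL), concentration c, apex t_R and width σ
  (default 0.05 min ≈ 3 s base-to-base UPLC peaks over a 12-min gradient).
- **Duty cycle**: fixed cycles (default 1.1001 s) holding one 250 ms MS1
  scan plus up to eight 100 ms MS2 events; a configuration whose events
  cannot fit in the cycle is rejected. MS2 event times are offset within
  the cycle, and eligibility (window containment) is evaluated at the
  event's own timestamp so scheduler output and extraction matching agree
  exactly.
- **PRM scheduling**: an entry is fragmented only when its *measured* MS1
  intensity strictly exceeds the threshold (default 50 cps) and the event
  lies inside its RT window; candidates are ranked by MS1 intensity (ties
  toward lower m/z) and capped per cycle (default 8).
- **DDA scheduling**: top-4 most intense precursors per 700 ms cycle, 30 s
  dynamic exclusion after 3 MS2 acquisitions per precursor.
- **MRM**: one transition per target (its most intense fragment) sampled on
  a uniform dwell grid (default 0.5 s).
- **Noise**: multiplicative log-normal with mean 1 and the configured CV,
  plus an optional additive baseline (default 0 so noiseless closed-form
  checks are exact). All randomness flows from one integer seed; identical
  seed and configuration give bit-identical spectra and truth tables.
- **In-source fragmentation**: glycosides lose a fraction
  f(T) = 1/(1 + exp(−(T − 450)/40)) of their signal to the aglycone as a
  logistic function of desolvation temperature T (°C). The midpoint
  (450 °C, where f = 0.5) and scale (40 °C) are configuration constants
  chosen to place the transition inside the 350–550 °C operating range of
  electrospray sources; they are simulator parameters, not instrument
  claims. The intact precursor is attenuated by (1 − f) in every mode and
  the cleaved fraction appears as an aglycone MS1 ion (at the partner
  target's m/z, or at −162.0528 Da — one anhydrohexose — when no partner is
  defined). Only the temperature axis is modelled; capillary voltage is a
  pass-through condition label.
- **MS1 content**: one centroid stick per species at the adduct m/z
  (M+H, M+NH₄, M+Na or M−H₂O+H offsets on the neutral monoisotopic mass) —
  no isotope envelopes, chimeric co-isolation, or detector saturation.

Every run returns a truth table (true concentrations, closed-form Gaussian
MS1 areas F·c·(1−f)·σ·√(2π), the exact MS2 scan ids emitted, applied
in-source fractions), which is what the extraction tests compare against.

**What passing simulator-based tests shows — and does not.** The simulator
demonstrates that the extraction, calibration and comparison machinery is
correct under its stated model: Gaussian peaks, stick spectra, log-normal
noise, deterministic scheduling. Real data additionally contains baseline
drift, tailing/fronting peaks, isotope envelopes, chimeric MS2, retention
drift between runs and detector nonlinearity; conclusions about those
effects cannot be drawn from these tests.

## Problem sizes in tests and the acceptance script

Scheduler and closed-form checks run on 1.2–3 min simulated gradients with
1–20 targets. The cross-mode agreement study uses 200 independent seeds,
each simulating a calibration series plus 10 samples × 3 dilutions in PRM
and MRM modes with a 3-analyte + internal-standard panel on an 8-min
gradient at 5 % noise — sizes chosen so the whole study completes in a few
minutes on one CPU while keeping ≥30 paired concentrations per fit. The
published-line recovery check uses 100 seeded replicates of the ten-level
series at 1 % noise. The shipped demo configuration (`examples/`) uses 4
samples and triplicate calibration and completes in seconds.

## Known limitations

- No chromatographic alignment, deconvolution of chimeric MS2, or
  isotope-pattern scoring; inclusion lists are assumed to be RT-calibrated.
- Vendor raw formats (.wiff, .raw) are not read; convert to centroided mzML
  first.
- Weighted Deming, Passing–Bablok and Bland–Altman analyses are out of
  scope; δ ≠ 1 Deming is available but untested against external software.
- The merit SD convention (replicate back-calculation at the lowest
  quantifiable standard) is one of several in use; results are not directly
  comparable to blank-based LODs.
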