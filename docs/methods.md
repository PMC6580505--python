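# Methods

This note documents the models, the synthetic data they are tested
against, the numerical choices, and the known limitations.

## The synthetic cohort

The generator emulates a biologged wolverine cohort at a sub-Arctic study
site (67.00°N, 17.67°E). Core body temperature for animal *i* at time *t*
is

    T_b(t) = 38.5 + A_s·cos(2π(DOY − 196)/L)            (annual cycle)
           + A_season·[(1−f)·cos(φ) + f·cos(2φ)]        (daily rhythm)
           + g_i(t)                                      (gestation)
           + fever(t) + ε(t)                             (events, noise)

with φ the phase anchored to local solar noon (24-h period), `f = 0.3` the
12-h harmonic weight (enough to create a secondary crepuscular maximum),
seasonal rhythm amplitudes winter 1.2 / spring 0.9 / summer 0.8 /
autumn 1.0 °C, annual amplitude `A_s = 0.15` °C peaking on DOY 196, and
ε stationary AR1 noise (ρ = 0.6 per 5-min step, marginal SD 0.15 °C).
These defaults are the study conditions the analysis is meant to recover: a
cohort mean of ≈38.5 °C, daily variation of ≈2–2.5 °C, a mid-July annual
peak, and season-dependent rhythm strength.

Pregnant females (77% of animal-years by default; recovery experiments use
50% so both classes are present) implant on a uniform day in DOY 5–25 and
ramp linearly down by 0.5 °C over a 45-day gestation, rebounding to
baseline over 3 days after parturition; the within-day rhythm amplitude is
damped by 40% during gestation (pregnant females show lower daily
variation). Fever days add +2 °C to every sample of the day
(Poisson, 0.5/animal-year). Artifacts replace isolated single samples with
uniform values in [30, 33.5) °C (Poisson, 2/animal-year, spaced ≥3 samples
apart so each is an isolated dip). 2% of samples are dropped uniformly at
random.

Activity is generated from the same circadian phase: per-axis Poisson
counts around `255·(1 + shape)·season_scale / 2`, summed and clipped to
0–510. The magnitude and noise model are conventions — the measurement
protocol fixes only the 0–510 range — so activity-based results are
qualitative. GPS fixes follow a mean-anchored random walk (~800 m steps,
3-hourly); after parturition a female's fixes collapse to N(den, 100 m)
for 30 days, which the denning-localization check should flag.

What the generator does **not** emulate: weather-driven T_a coupling (only
a helper sinusoid −12…+12 °C is provided), behaviourally-driven activity
bouts, logger drift, block dropout (an independent-uniform missingness
null is the default), or between-animal variation in baseline temperature
beyond what random effects absorb. Passing recovery tests therefore show
the estimators work when the assumed structure holds, not that field data
meet those assumptions.

## QC rules

Operationalizations where the protocol leaves detail open: "week of
capture" is 7 calendar days starting at the capture date; "immediate
return to baseline" is a run of ≤2 consecutive sub-34 °C samples with both
flanking samples at or above threshold (longer excursions are reported as
possible true hypothermia, not corrected); days with fewer than 50% of
expected samples are excluded as sparse; the fever threshold (daily mean
≥ 40.0 °C) is inclusive. Timestamps are stored UTC; day boundaries and
hour-of-day use a configurable local timezone (default Europe/Stockholm)
because daily patterns are referenced to local light. Daily means include
imputed values; daily-variation analyses exclude days containing them.

## Pregnancy dating

PELT minimizes Σ RSS + β·m exactly for the Gaussian change-in-mean cost
(the pruning is lossless for this cost, verified against an exhaustive
dynamic program). The default penalty is MBIC-like, β = 3·ln(n)·σ̂², with
σ̂² from the median absolute first difference (robust to the very mean
shifts being detected). Because the gestational decline is a shallow ramp
(~0.011 °C/day), its first changepoint lands a few days into the ramp; the
onset is therefore refined by a flat-then-linear broken-stick least-squares
fit in a ±20-day neighbourhood, taking the break day. A decline qualifies
as gestation when it starts in DOY 1–60, accumulates ≥0.3 °C and lasts
≥20 days — thresholds chosen to sit well inside the expected signal
(0.5–0.8 °C over ~45 days) and above daily-mean noise.

Parturition is the first day whose cumulative rise from the gestation
trough reaches 0.25 °C *and* whose following 5-day median returns to
within 0.2 °C of the pre-implantation baseline. Using the median (not the
maximum) makes a single elevated day — e.g. a mild fever during late
gestation that slips under the 40 °C exclusion — unable to fake a rebound.
With the generator's 3-day recovery ramp this detector fires one day after
the true parturition day on noiseless data; the reported decline depth
therefore uses the trough over the 3 days before the detected rebound
rather than literally the day before. The depth reference is the same
record's December mean when ≥15 December days exist, else the two
pre-implantation weeks.

A decline without a detectable rebound (e.g. logger retrieved
mid-gestation) is classified undetermined, not pregnant. GPS denning
localization (all fixes of a trailing 5-day window within 500 m of their
centroid, great-circle) is advisory evidence only and never overrides the
temperature call. Two-year-old females run through the same rule with no
special-casing.

## Annual smooth models

The Gaussian model is penalized least squares on a design with: intercept;
a cyclic cubic B-spline in DOY (k = 40 basis functions, curvature
penalty); a pregnant offset; a difference smooth (same basis) applied to
pregnant rows, centred over pregnant rows for identifiability; and
per-animal random intercepts and DOY-slopes as ridge-penalized columns.
This is intentionally not a full mixed-model GAMM: smoothing parameters
come from GCV (not REML), random effects are ridge-penalized fixed terms,
and the AR1 structure is handled by iterated Cochrane–Orcutt pre-whitening
within animal (convergence |Δρ| < 1e-4, max 20 iterations). The
inferential structure — reference smooth, factor-smooth difference,
pointwise 95% CI exclusion — is preserved at tractable complexity.

Numerical choices that matter:

* **Basis dimension.** k = 40 for the DOY smooths (~9-day knot spacing).
  The gestation difference curve has a sharp corner at the parturition
  rebound; coarser bases (k ≤ 30, ≥12-day knots) cannot represent its
  trough to better than ~0.1 °C even unpenalized, which under-smoothing
  diagnostics (the standard k-check) flag immediately. k = 10 for
  hour-of-day smooths.
* **Cyclic domain.** DOY lives on [1, 366] with period 365; DOY 366 (leap
  day) wraps onto DOY 1. The annual smooths are cyclic — physically the
  year wraps — though this is an open choice the original protocol does
  not pin down.
* **GCV with γ = 1.4.** Plain GCV slightly undersmooths the difference
  term, scattering spurious significant days; inflating each effective df
  by 1.4 in the GCV score is the standard remedy and is applied to both
  the Gaussian and binomial selectors.
* **ρ estimation.** The lag-1 autocorrelation is computed from
  within-animal residuals detrended by a 31-day running mean. Without
  detrending, smooth per-animal misfit (individual gestation timing the
  population curve cannot absorb) masquerades as ρ ≈ 0.7 and the resulting
  over-whitening biases the difference curve toward zero.
* **CIs.** Penalty-informed (Bayesian) covariance σ²(XᵀX + S_λ)⁻¹ with
  normal quantiles, appropriate at these sample sizes.

The binomial variant (rhythm probability) drops the state terms and AR1,
and fits by penalized IRLS (logit link, η clipped at ±15 for separation
robustness), selecting λ on a coarse grid by a deviance-based GCV.
Where one class saturates a season entirely (common when rhythm detection
is near-certain in summer) the curve pins to the boundary and its CI there
is uninformative — the winter trough remains well estimated.

On recovery runs with the default cohort, note that the estimand of the
difference-curve minimum is the *group-mean* gestation curve: with
implantation staggered over DOY 5–25, individual 0.5 °C ramps average to a
group trough of ~0.38–0.45 °C, and the spline approximation of its corner
costs a few hundredths more. Random draws with unusually wide stagger can
push the recoverable trough shallower than 0.35 °C; that reflects the
estimand, not the estimator.

## Rhythm detection

The classical normalized Lomb–Scargle periodogram (τ formulation, power
normalized by the sample variance with ddof = 1) is evaluated on a 0.1-h
period grid over [2, 30] h (281 points). The rolling scan centres a
15-day window on each day (edges keep whatever of the ±7 days exists,
minimum 8 days span and 50% coverage; skipped windows are omitted — absence
of data is not absence of rhythm). For efficiency the window sums are
assembled from cached per-day partial sums (all the τ-form terms are
additive over samples); this is exact algebra, tested to machine precision
against the direct computation, and makes the scan ~35× faster than
recomputing trigonometry per window.

Significance uses the analytic white-noise null
p(z) = 1 − (1 − e^(−z))^M with M the number of independent Fourier
frequencies in the scanned band, M = span·(1/p_min − 1/p_max), clipped to
[1, n]. The empirical false-positive rate on white noise is ~5–6% at
α = 0.05. The highest significant peak is rounded to the full hour
(half up); 24 → "h24", 12 → "h12", otherwise "other".

**Known limitation (inherited from the method):** the white-noise null is
strongly anti-conservative under serial correlation. On rhythm-free AR1
noise at the generator's defaults, most windows contain *some* nominally
significant peak — but those peaks scatter over the period band, so the
quantity the analysis consumes (the 24-h/12-h classification) remains
controlled: ≈3% of rhythm-free windows classify as h24/h12. Absolute
"significant rhythm" prevalences are therefore method-sensitive; the 24-h
and 12-h prevalences and their annual probability curves are the robust
outputs. A permutation-based p-value (`monte_carlo_p_value`) is provided
for sensitivity analysis.

A closed-form check of the threshold inversion: at α = 0.05 and M = 100,
z* = −ln(1 − 0.95^(1/100)) = 7.576.

## Solar geometry

Low-precision NOAA-style ephemeris (Fourier series for declination and the
equation of time; no ΔT, nutation, or topographic/atmospheric corrections),
accurate to well under 0.3° of altitude. Sunrise/sunset are the solar
centre at −0.833° — the standard top-edge-plus-refraction definition,
which reproduces the site's 1.5-h December minimum day length (a −1°
definition would give ≈1.8 h). Civil dawn/dusk at −6°. Events are located
by sign-change bracketing on a 1-minute grid refined by bisection to ~1 s;
day length integrates time-above-horizon across the UTC day, which remains
correct under polar regimes and rise/set pairs that straddle midnight.

## Energetics

Below thermoneutrality, heat loss scales with the body–ambient gradient
(Newtonian conductance), so a sustained reduction from `tb_ref` to
`tb_low` at ambient `ta` saves `(tb_ref − tb_low)/(tb_ref − ta)` of
thermoregulatory cost: 38.5 → 35.8 °C at −10 °C gives 2.7/48.5 = 5.57%. A
Q10 metabolic alternative is available behind a flag (`method="q10"`); it
answers a different physiological question (temperature sensitivity of
tissue metabolism, ≈22% at Q10 = 2.5) and is not the default. No
conductance values, BMR scaling or wind effects are modelled.

## Problem sizes

Test and acceptance runs are sized for a single CPU: the recovery cohort
is 10 animals × 1 year at 5-min sampling (50% pregnancy so both classes
appear); changepoint oracle equivalence uses 200 random series of n ≤ 60;
Lomb–Scargle reference agreement uses 20 irregular series; type-I control
uses 500 independent 15-day windows at 15-min sampling; the
h24-classification rate is measured on 3 animals' full-year scans (the
per-window classification is animal-independent by construction); null CI
coverage uses 30 replicates of a 4-animal design. The full synthetic
pipeline (3 animals) runs in ~10 s; the whole suite in ~1 minute.
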