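# Methods

This note records the model, the conventions and the genuinely open design
choices behind `dbprisk`, in the order the pipeline runs.

## Censored concentrations

Concentrations reported below the analytical limit of detection (LOD) are
left-censored. The package uses simple LOD/2 substitution — the standard
screening convention for environmental monitoring data — and deliberately
nothing more sophisticated (no maximum-likelihood or
regression-on-order-statistics estimators): the assessment this package
implements is defined in terms of the substitution rule, and substituting
half the LOD is a known source of *over*-estimation for mostly-censored
analytes, which is conservative for a screening assessment. Detection
status is stored as a flag separate from the magnitude, so detection rates
are unaffected by imputation, and `impute_censored` is idempotent.

LODs are entered in µg/L (the scale on which analytical methods report
them: TCM 0.032, DBCM 0.015, BDCM 0.016, TBM 0.041, DCAA 2.0, TCAA 1.0)
and converted to mg/L at the imputation boundary; everything downstream is
mg/L. "Detected" is defined by the flag, not by magnitude: a detected
value below some other analyte's LOD is still detected.

## Dose and risk model

The chronic ingestion dose is the US EPA screening form
`ADD = C·IR·EF·ED / (BW·AT)` with exposure frequency EF = 365 days/year,
exposure duration ED = 3 years per age group, and averaging time
AT = ED × 365 days. EF·ED/AT ≡ 1, so ADD = C·IR/BW; the full form is kept
in code (the parameters remain visible and overridable) and the algebraic
reduction is asserted in tests to machine precision.

Carcinogenic risk is CR = SF·ADD·ADAF with the slope factor SF from
IRIS/RAIS. Age-dependent adjustment factors follow the rule that a factor
of 3 applies through the 15th year and 1 for ages 16–17 (rather than the
canonical EPA 2-to-<16 schedule — the assessment's own stated rule is
encoded, in `ExposureGroup`, not hard-wired into the formulas). For the
15–17 group the effective multiplier is the exposure-duration-weighted
average (3×1 year + 1×2 years)/3 years = 5/3, which the implementation
applies as a single `adaf_effective`; the equality with the explicit
weighted average is exact and tested. The hazard quotient is HQ = ADD/RfD
(no ADAF). Totals across the six analytes are simple sums (CR_t = ΣCRᵢ,
HQ_t = ΣHQᵢ), i.e. dose additivity without interaction.

Exposure parameters (IR in L/day, BW in kg) are the handbook values for
four age groups × {male, female, combined} — twelve exposure groups. Male
and female risk vectors are derived from the *same* water samples with
different (IR, BW) constants; the gender contrast in the test battery
compares them with a two-sample Mann–Whitney procedure, which should be
read with the caveat that the underlying concentration data are paired.

## Summary statistics and rounding

Medians use the mean-of-the-two-central-order-statistics convention for
even n; Q_R = Q3 − Q1 with linear-interpolation quartiles (numpy's
default). Quantile conventions differ across software and Q_R values are
treated as descriptive, not as pinned reference values.

`summarize_risks` reports, per stratum, both aggregates that can be called
"total risk": (a) the sum of per-analyte medians and (b) the median of
per-sample summed risks. They differ in general (the median is not
additive). The totals *row* carries (a), the convention under which
multi-pollutant screening tables tally their printed per-analyte column;
(b) is kept in `median_cr_samplesum`/`median_hq_samplesum` columns.

Report tables (`format_risk_report`) print CR ×10⁻⁶ and HQ ×10⁻² at three
decimals, round-half-even, and re-tally totals rows from the **rounded**
per-analyte entries. This makes the printed total exactly the sum of the
printed rows — at full precision the 6–8 CR_t is 75.9975×10⁻⁶, which
would round to 75.998 while the rounded rows sum to 75.997; screening
reports tally the printed column, and the report follows that convention.
Internal computation is full precision throughout.

## Rank statistics

All four tests are tie-aware (mid-ranks, standard tie-corrected
variances), use no continuity correction, and report two-sided p-values.
They are implemented directly rather than delegated, because the package
pins down exact conventions that library routines either do not expose or
handle differently: the signed Z form of the Mann–Whitney test (positive
Z ⇒ first sample larger; callers fix the order — dry first, male first,
surface first), the Jonckheere–Terpstra test (positive Z ⇒ increasing
along the stated group order; not in scipy at all), and the degenerate
all-constant input, which returns the uninformative result (Z = 0 or
H = 0, p = 1) instead of a 0/0 failure. scipy.stats serves as the
independent cross-check in the test suite (exact agreement with
`scipy.stats.kruskal` and `scipy.stats.spearmanr` on non-degenerate data),
and exhaustive permutation enumeration is the oracle for the U and JT
counting statistics at small n. The normal approximations are only
order-of-magnitude accurate at n ≤ 8 — expected, and irrelevant at the
per-stratum sizes (≥ 32) the pipeline feeds them.

The Spearman matrix is pairwise-complete, r is the Pearson correlation of
mid-ranks, p uses the t approximation with n − 2 degrees of freedom, and
significance tiers mirror the usual star flags (\* p<0.05, \*\* p<0.01).
Pairs involving a constant margin (zero rank variance) are reported as
not available rather than zero. No multiple-testing correction is applied
anywhere in the battery.

## Synthetic study generator

The generator emulates the monitoring design, not the water chemistry.

**Margins.** Season, stage, source and disinfectant labels are fixed-count
vectors shuffled independently with the seeded generator, so every
categorical margin is matched *exactly* for every seed (default: 886
samples; 442/444 dry/wet; 138/550/198 finished/terminal/secondary; 854/32
surface/ground; 718/112/52/4 by disinfectant). The campaign publishes only
margins, so no joint structure between labels is modeled (labels are
independent); cross-tabulated counts in generated data are a consequence
of that choice, not data. Waterworks ids are assigned round-robin over 69
ids with no waterworks-level random effect.

**Concentrations.** Per analyte, censoring is Bernoulli with probability
1 − detection rate, independent of magnitude; detected values are
log-normal, clipped to [LOD, observed maximum]. The log-normal parameters
are solved (1-D Brent root find, tolerance ~1e-12) so that the
**post-imputation mixture** — the censored point mass at LOD/2 plus the
detected distribution — has the published *overall* median and IQR. This
is the quantity the campaign's summary table actually prints, and it is
what makes the full pipeline's median risks converge to the worked-example
values: calibrating the detected distribution alone would misplace the
overall median whenever the detection rate is near 50% (DCAA, 53.16%,
would land ~3× low). For majority-censored analytes (TBM 35.10%, TCAA
37.92%) the overall median *is* the imputed value by construction, and the
detected distribution is anchored instead by the mixture's Q3
(imputed + IQR) and by treating the observed maximum as its 99.5th
percentile (closed form in (µ, σ)). Clipping, rather than rejection
sampling, is used at the bounds so that all interior calibrated quantiles
are preserved exactly. An overall median below the LOD combined with a
detection rate above 50% is reported as an infeasible calibration.

**Season and stage effects.** TCM, DBCM and BDCM carry multiplicative
wet/dry and finished→terminal→secondary effects, defaulting to the ratios
of the published per-stratum medians; the factors are log-centred (season
50/50, stage by the design's stage proportions) so the overall marginal is
approximately preserved. Analytes whose per-stratum medians are themselves
imputed values (TBM, DCAA, TCAA in at least one season) default to
identity factors — a ratio of substitution constants is not an effect
size. Empirically, at n = 50,000 the generated overall medians sit within
~1.2% of their targets and detection rates within 0.15% absolute.

**Water-quality parameters.** pH is bounded normal (median 7.20, bounds
6.50–8.46); the permanganate index (median 0.69, IQR 0.46 mg/L) and free
chlorine (median 0.26, IQR 0.30 mg/L) are bounded log-normal. No pH IQR is
published; the default 0.40 is taken from the middle of the per-stratum
spread (0.27–0.61). WQPs are generated independently of the DBP values, so
generated data reproduce marginal distributions but **not** the real
correlation structure between DBPs and WQPs (or among DBPs): passing
correlation-matrix tests on synthetic data demonstrates the machinery, not
the chemistry. Likewise the generator's season/stage effects reproduce the
*direction and rough size* of published contrasts (e.g. wet-season TCM
above dry-season), not their exact Z/H statistics, which depend on the
unavailable raw data.

**Scaling.** `scaled_design(n)` rescales all margins proportionally with
largest-remainder rounding, for Monte-Carlo checks of the calibration
(the test suite uses n = 50,000, where quantile sampling error is well
inside the ±5% tolerance it asserts).

## Determinism and numerics

A single `numpy.random.Generator` seeded from the user's seed drives the
whole generation in a fixed order, so identical seed + configuration gives
byte-identical CSV output. The calibration root finds use Brent's method
with near-machine relative tolerance; the ND-median regime is closed-form.
Degenerate inputs are contracts, not crashes: empty sample collections and
empty strata raise explicit errors; a single-sample stratum reports its
value with Q_R = 0; all-censored analytes summarize to detection rate 0
and median LOD/2.

## Problem sizes used in the checks

The worked example is a single pseudo-sample carrying the published median
concentrations (closed-form, sub-second). Generator recovery is checked at
n = 50,000 samples (≈3.6 M sample × analyte × group risk records through
the full pipeline); structural properties (margins, idempotence,
equivariance) on studies of a few hundred samples; enumeration oracles at
total n ≤ 8, where exhaustive permutation is exact and instant.

## Known limitations

- Ingestion route only; no dermal or inhalation exposure, no multi-route
  aggregation, and no adjustment for boiling before consumption (which
  reduces volatile THM intake) — risks are conservative in that respect.
- LOD/2 substitution biases mostly-censored analytes (TBM, TCAA) upward.
- No Monte-Carlo uncertainty propagation; point estimates with stratified
  medians/IQRs only.
- The generator draws analytes independently; it cannot be used to study
  between-analyte correlation or waterworks-level clustering.
- The gender Mann–Whitney contrast treats paired vectors as independent
  samples (see above).
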