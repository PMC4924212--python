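# Methods

## The measurement chain

Two estimates of body composition are produced per child and compared.

**Criterion (3C model).** Total body water is measured by isotope dilution:
each tracer's urine-enrichment series is assumed mono-exponential after
equilibration, `E(t) = E₀·e^(−kt)`, and is fitted by unweighted OLS on the
log scale (no outlier rejection). The zero-time enrichment is converted to
a dilution space by the plateau principle, `N = dose_mol·(1/E₀ − 1)·M_w`
with `M_w = 0.018015 kg/mol`. This is a deliberate simplification of
laboratory practice: isotope-specific fractionation corrections beyond the
standard space-to-water divisors are not applied, because those divisors
(N_D/1.041, N_O/1.007, averaged) are the only corrections the validation
design itself uses. Enrichments must be supplied as excess mole fraction
above the pre-dose baseline; delta-per-mil conversion from mass
spectrometry is out of scope. The N_D/N_O ratio is sanity-checked against
1.039 ± 3·0.008 and flagged, never corrected. Fat mass then follows from
`FM = 2.220·BV − 0.764·TBW − 1.465·BW`. TBW enters in kg of water and the
coefficient on TBW assumes litres; body water density is taken as 1 kg/L,
the universal convention at these precisions.

**Test (BIA).** The impedance device outputs BF% directly;
`FM = BF%/100·BW` and `FFM = BW − FM`. Raw impedance is not modelled.

A negative FM or a BF% above 60 marks mutually inconsistent inputs; results
are flagged, never clamped, and flagged subjects are excluded from the
cohort statistics only on request (default: keep everyone).

## Agreement statistics

All statistics use the n−1 sample SD. Limits of agreement are the mean
difference ± exactly 2·SD of the differences — the convention of the
validation design this package reproduces — not 1.96·SD. Proportional bias
is the OLS trend of difference on average, with significance taken from the
Pearson correlation of (average, difference) on n−2 df. The calibration
regression puts the criterion on the y-axis and the test method on the
x-axis; its direction is fixed by the calibration argument below. Degenerate
inputs (zero-variance differences or averages) yield NaN plus a flag rather
than an exception, so batch runs survive pathological variables. No
multiple-testing correction is applied. Because `FM + FFM = BW` holds
exactly under both methods, the FFM agreement block is the mirror image of
the FM block (negated bias, identical SD); the test suite asserts this
duality cohort-wide.

## Classification capacity

Subjects are ranked by the variable under each method (stable sort; input
order breaks ties, which are measure-zero under the generator) and cut into
g contiguous groups; when g does not divide n the remainder is assigned
one-per-group starting from the lowest group, so n = 40, g = 3 gives
14/13/13. The offset table (test group − reference group) is invariant
under strictly increasing transforms of either method's values, so it
isolates ranking skill from calibration bias. Offsets beyond ±2 appear
naturally when g > 3; the ±2 cap in the tertile case is a consequence of
g = 3, not a rule. Group bounds are reported as the observed min/max per
group, which sidesteps any open/closed-interval convention.

## The synthetic-cohort generator

The generator emulates a homogeneous cohort of healthy ~5.5-year-olds with
paired BIA/3C body-fat structure. Its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `bia_bf_mean`, `bia_bf_sd` | 19.4, 3.9 % | BIA BF% distribution |
| `bias_intercept`, `bias_slope` | 2.974, 1.142 | linear BIA→3C calibration |
| `bias_noise_sd` | 3.29 % | residual SD around the calibration (SEE) |
| `weight_mean`, `weight_sd` | 20.5, 4.2 kg | body weight |
| `height_mean`, `height_sd` | 114.0, 4.0 cm | height |
| `hydration_mean`, `hydration_sd` | 0.765, 0.01 | hydration of FFM |
| `nd_no_ratio_mean`, `nd_no_ratio_sd` | 1.039, 0.008 | deuterium/oxygen-18 space ratio |
| `seed` | 1 | single RNG stream |

The bias model is read as 3C = f(BIA) because only that direction
reproduces the criterion moments from the BIA moments: mean
2.974 + 1.142·19.4 = 25.13, SD √(1.142²·3.9² + 3.29²) = 5.54 and
r = 1.142·3.9/5.54 = 0.804 — consistent with the reported 25.1 ± 5.5 and
r ≈ 0.81 (the reported r = 0.809 and R² = 0.645 ⇒ r = 0.803 bracket it;
tolerances are set to cover both).

Draws are truncated to physiological ranges chosen once to cover the
observed study ranges: BIA BF% [10, 50], 3C BF% [8, 55], weight [12, 40] kg,
height [100, 130] cm, age [5, 6] y. A numerical subtlety: the BIA lower
bound sits only 2.4 SD below the mean, and plain rejection sampling there
would shift the mean by ≈ +0.09 and shrink the SD to 3.78 — enough to break
the calibration. Each truncated normal is therefore parameterised by its
*truncated* moments: the underlying (μ, σ) are solved numerically so that
the truncated draw has exactly the requested mean and SD in distribution.
The criterion BF% is formed by redrawing only the noise term for the rare
out-of-bounds subject, keeping the subject's BIA value.

Weight and height are bivariate normal with correlation 0.7 (a typical
pediatric value; the validation design is silent on this covariance) and
BF% is drawn independently of body size. Consequently BF%-scale statistics
are calibrated but kg-scale ones (FM, FFM differences) are only
structurally correct, not numerically matched — the FM/FFM blocks of any
report are therefore illustrative. Hydration of FFM (0.765 ± 0.01, the
standard pediatric value) is *not* a model assumption of the 3C method; it
is used only to manufacture raw inputs (TBW, body volume, dilution spaces)
that are self-consistent, by inverting the 3C equation and the two-space
average. The optional enrichment-series synthesiser uses the dosing
protocol of 0.14 g/kg ²H₂O and 0.35 g/kg H₂¹⁸O (molar masses 20.028 and
20.015 g/mol) and elimination rates k_D = 0.10/day, k_O = 0.12/day, typical
of the high water turnover of 5-year-olds.

What the generator does **not** emulate: sex-specific bias, growth or
longitudinal change, BF%–size covariance, device-level measurement error
structure (the linear-plus-noise bias is a reduced form), and non-Gaussian
tails. Passing tests therefore demonstrate that the *pipeline* recovers the
parameters of this reduced-form data-generating process, not that any
particular BIA device behaves this way on real children.

## Problem sizes and numerical choices

Calibration checks use one cohort of 200,000 subjects (a few seconds; the
Monte-Carlo SE of the recovered mean is ≈ 0.012 BF%). Classification
capacity is averaged over 2,000 cohorts of n = 40, drawn as one vectorised
batch of 80,000 iid subjects and sliced — identical in distribution to
2,000 independent cohorts. Under the default calibration the mean tertile
concordance is ≈ 65% (SD ≈ 8 across cohorts) with ≈ 98% within one group.
Algebraic identities (mass balance, round trips) are asserted at 1e−9 and
the statistics against a direct-formula oracle at 1e−10. All randomness
flows from a single integer seed through one NumPy Generator; reruns are
byte-identical. Report files round to 1 decimal at presentation only;
machine-readable outputs keep full precision.

## Known limitations

- The dilution-space formula is the plateau-principle approximation; real
  laboratory pipelines apply tracer-specific corrections upstream.
- The calibration regression direction (criterion on test) is a modelling
  choice; users wanting prediction equations for BIA from the criterion
  should swap the sample's roles explicitly.
- Tertile concordance from a single n = 40 cohort has an SD of ≈ 8
  percentage points; single-cohort values should not be over-read.
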