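# Methods

## Model and assumptions

The calculator treats the post-vitrectomy eye as a closed, isothermal gas
system inside a rigid boundary and asks how much an intravitreous gas or
air bubble would expand on a direct trip to a higher altitude.

**Cavity geometry.** The vitreous cavity is idealised as an oblate spheroid
of total volume V = 4.5 ml, the conventional adult value. The bubble is
buoyant, so it forms a cap at the superior pole bounded below by a
horizontal fluid/gas interface. Let *h* ∈ [0, 1] be the fraction of the
cavity's vertical diameter occupied by gas, measured downward from the
superior pole (this matches both the surgeon's fundoscopic judgment and the
patient's perceived boundary between blurred lower and clear upper visual
field — image inversion puts the gas-blurred region in the lower field).
An axis-aligned affine scaling maps the unit sphere onto any spheroid with
one axis vertical while multiplying every horizontal slab volume by the
same constant, so the volume fraction of the cap depends only on the
normalised height:

    f(h) = h²(3 − 2h),     V₁ = V · f(h).

This removes an unidentifiable shape parameter: the spheroid's aspect ratio
never enters, only its total volume. f is strictly increasing, satisfies
f(h) + f(1−h) = 1, and is inverted numerically by bracketed root-finding
(Brent's method, tolerance 1e−12 in h); no closed-form cubic root is
needed.

**Atmosphere.** Altitude z maps to ambient pressure with the International
Standard Atmosphere troposphere formula

    P(z) = P₀ (1 − L z / T₀)^k,

with defaults P₀ = 101.325 kPa, L = 0.0065 K/m, T₀ = 288.15 K and
k = gM/(RL) = 5.25588, valid on −500 m ≤ z ≤ 11 000 m. All four constants
are configurable (YAML/JSON keys `sea_level_pressure_kpa`,
`lapse_rate_k_per_m`, `sea_level_temperature_k`, `exponent`) so an
alternative barometric relation can be matched exactly. Weather-driven
pressure variation is ignored: altitude is the sole driver. Pressures are
carried in kPa internally; mmHg conversion uses the exact factor
1 kPa = 7.500617 mmHg. The closed-form inverse z(P) is provided for
reporting and round-trip testing.

**Expansion and risk.** Boyle's law gives the unconstrained destination
volume V₂ = V₁ P(z₁)/P(z₂) and the signed excess ΔV = V₂ − V₁ (negative
for descent). No eyewall back-pressure or compensation mechanism
(choroidal compression, scleral expansion, accelerated aqueous outflow) is
modelled; the intended scenario is immediate, direct travel, so V₂ is an
upper bound on the true expanded volume. The clinical readout is the ratio
r = ΔV / V_AC, where V_AC is the normal anterior-chamber volume, default
0.20 ml (typical adult anatomic value; configurable). r is mapped to an
ordered category: r ≤ 0 → "none"; then cut points at 0.5 and 1.0 delimit
low / moderate / high with a closed-left convention (a ratio exactly at a
cut point takes the higher category). The cut points are exposed
configuration, not validated clinical thresholds: no published mapping from
ratio to wording exists, and nothing else in the package depends on the
labels — all quantitative outputs are ΔV and r themselves.

## Agreement statistics

Paired surgeon/patient interface judgments (percent, index-matched) are
compared with:

- **Bland–Altman.** Differences are taken as surgeon − patient (chosen so
  that a slightly lower surgeon median yields a negative bias). Bias is
  their mean, SD uses the n−1 denominator, and limits of agreement are
  bias ± 1.96·SD. The 1.96 multiplier (not a t quantile) is the
  conventional 95% band and is exposed as a parameter. A difference-vs-mean
  scatter with bias/LoA overlay is rendered to SVG/PNG.
- **Wilcoxon matched-pairs signed-rank test**, two-sided, on the same
  differences. Zero differences are dropped (Wilcoxon's convention,
  matching common statistical packages); tied absolute differences receive
  average ranks. For ≤ 25 nonzero differences the exact null distribution
  of W⁺ is enumerated by dynamic programming over doubled ranks (average
  ranks are half-integers) and the two-sided p is 2·min(P(W≤w), P(W≥w)),
  capped at 1. Above 25, a normal approximation with continuity correction
  (0.5 toward the null mean) and the standard tie correction to the
  variance is used; at n = 15 the two routes agree within 0.02 in tests,
  and scipy's implementation serves as an independent cross-check. The
  all-zero case returns p = 1 with an explicit degenerate flag.
- **Descriptives.** Median (mean of the central two for even n) with
  min/max, and counts/proportions per level for the two 5-point Likert
  usability items. A normality screen is unnecessary here: it would only
  choose between descriptive formats, and the package always reports
  median (range).

## Synthetic cohorts

The generator emulates the structure of the validation study so that every
pipeline stage is testable without patient data. Defaults (all
configurable): n = 50 patients from a low-altitude surgical centre (origin
fixed at 10 m); surgeon-judged heights uniform on 9–78%; patient judgment =
surgeon − (bias + Gaussian noise) clipped to [0, 100], with bias −0.3% and
SD 2.8% — the SD is back-solved so the default LoA width ≈ 2·1.96·2.8 ≈ 11%
matches the reported agreement band, an emulation choice rather than a
measured quantity; destinations drawn from a pool of {Guangzhou 10 m,
coastal uniform 0–150 m, Kunming 1842 m, Guiyang 1277 m, Lhasa 3490 m} with
weights 0.12/0.70/0.10/0.06/0.02 (city weights follow the observed 5, 3
and 1 of 50 provenance counts); travel modes airplane/train/car-bus at
0.38/0.30/0.32 with 11/15 of train travellers on high-speed rail; Likert
responses concentrated on levels 4–5. Ages are uniform integers 18–70, sex
is 60% male, and visual acuity is sampled from a CF-to-20/25 list. A single
`numpy.random.default_rng(seed)` stream drives all draws; the seed is
recorded in the cohort provenance.

What the generator does **not** emulate: diagnosis-specific fill levels,
gas absorption over postoperative days, judgment error that grows with
bubble size (noise is homoscedastic and Gaussian; real perceptual error may
be heavier-tailed), or any correlation between destination altitude and
travel mode. Passing parameter-recovery and calibration tests therefore
demonstrates the correctness of the statistical machinery under the stated
noise model, not the field accuracy of patient self-assessment. Because the
coastal component of the default pool is capped at 150 m, the generated
median destination altitude falls below the ~150 m seen in the study; the
pool is a marginal emulation, not a fitted distribution.

## Numerical choices

- Interface heights are accepted as percentages at every boundary (CLI,
  CSV) and converted to fractions on ingestion; the fraction is the
  internal unit.
- Geometry inversion: Brent root-finding on [0, 1], xtol 1e−12; endpoint
  volumes return exactly 0 or 1.
- Domain checks raise typed errors naming the offending value and valid
  range (altitudes outside [−500, 11000] m, heights outside [0, 100]%,
  negative volumes, pressures outside the troposphere band). Cohort rows
  report 1-based row numbers and field names; a file with any invalid row
  is rejected as a whole rather than silently thinned.
- Exact Wilcoxon enumeration is O(n · Σ2rᵢ) ≤ O(n³) in time and memory
  (≤ 650 support points at n = 25), so the ≤ 25 cut-off is conservative.
- Chart rendering fixes the SVG hash salt and strips the date metadata so
  output is byte-identical for a fixed input.
- Test problem sizes: the Wilcoxon null calibration uses 2000 simulated
  cohorts of n = 50; parameter recovery uses n = 5000 pairs; the geometry
  slab-integration oracle uses 2·10⁵ midpoint slabs. These sizes give
  Monte-Carlo standard errors comfortably inside the asserted tolerances
  while keeping the whole suite in the seconds range.

## Known limitations

- V₂ ignores eyewall compliance and ocular compensation entirely, so the
  risk ratio overstates the true steady-state expansion; it is a screening
  quantity, not a predicted IOP in mmHg.
- The 4.5 ml cavity is a population default; highly myopic (enlarged) or
  unusually small globes deviate, and no biometry-based correction is
  offered.
- The risk-category cut points are placeholders; clinical wording should
  not be derived from them without validation.
- The barometric model is the standard atmosphere: cabin pressurisation
  schedules and weather are outside its scope (a pressurised cabin can be
  represented by passing the equivalent cabin altitude).
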