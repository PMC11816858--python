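# Methods

## Dose model

The absorbed dose to a cell culture at the irradiation position of a
thermal column is

    D_tot = (R_bg + C_B · R_B) · t_irr · P / P_max

with `R_bg` the background dose rate at maximum reactor power `P_max`
(sum of hydrogen-scatter, ¹⁴N(n,p)¹⁴C and γ-ray contributions), `R_B` the
¹⁰B(n,α)⁷Li dose rate per ppm of ¹⁰B, `C_B` the cellular boron
concentration in ppm (µg ¹⁰B per g cell mass), and `t_irr` the irradiation
time. The model assumes the thermal flux — and hence every dose-rate
component — is strictly proportional to reactor power, which also gives the
flux conversion `Φ_t = 4.8×10⁷ cm⁻² s⁻¹ kW⁻¹ · P` (calibrated from the
9.60×10⁸ cm⁻² s⁻¹ flux at 20 kW).

Constants are tabulated in mGy/s at `P_max` = 250 kW for two geometries
(T25 flask monolayers; spheroids in 96-well plates); all mGy→Gy conversion
happens in a single place in `dosimetry`. The tabulated background
components carry printing round-off (they sum to within 0.01% of `R_bg`,
not exactly); the component decomposition rescales the split to `R_bg` so
components always sum to `D_tot` exactly.

Statistical uncertainty is first-order propagation treating `t_irr` and
`P` as exact:

    σ_stat = (t_irr · P / P_max) · √(σ_Rbg² + C_B²σ_RB² + R_B²σ_CB²)

The systematic uncertainty (sensitivity of the transport calculation to the
assumed elemental composition of the cells, chiefly nitrogen) is an *input*
carried through reports, never derived here — deriving it requires
re-running the Monte-Carlo transport, which is out of scope.

Inverse planning is closed-form (`P = D·P_max/((R_bg+C_B·R_B)·t)` and the
symmetric expression for `t`); a plan needing more than `P_max` raises an
infeasibility error carrying the required power. Doses classify into the
2 Gy ("lower") and 6 Gy ("higher") reference groups by nearest reference;
the 4 Gy midpoint goes to "lower" — an arbitrary, fixed, tested tie rule.

**Known discrepancy.** Recomputing the published 2D planning doses from
the published mean 2D constants gives values ~1.4× larger than printed
(e.g. 2.20 vs 2.05 Gy total; 0.47 vs 0.33 Gy boron-free); all four
spheroid rows reproduce within ~1%. Whether the printed 2D doses used
per-flask rates or a different effective background is not determinable
from the published record. The package ships the 2D constants for forward
use, asserts only the spheroid rows in verification tests, and surfaces
the discrepancy as a warning in generated reports.

## ICP-MS quantification

The calibration standard contains boron at natural isotopic abundance
(f₁₀ = 0.199) with concentrations stated as total boron, while samples are
loaded with a monoisotopic ¹⁰B compound; both are measured on the ¹⁰B
mass. Reading a monoisotopic sample off that curve overstates its ¹⁰B by
1/f₁₀, so the apparent concentration is multiplied by f₁₀ — this direction
of the correction is inferred from the calibration setup (the exact
arithmetic is not published) and f₁₀ is configurable. Blank is subtracted
before the curve; values negative beyond the noise floor flag "below
detection" and clamp to zero with a warning rather than propagate negative
concentrations. The 10 mg/L QC standard warns above 5% drift (no published
tolerance; 5% is a conventional ICP-MS stability band). Calibration is
ordinary least squares (scipy), requiring ≥2 distinct concentrations.

## Comet statistics

Per-cell %tail-DNA values live in [0, 100]. The uncertainty of a sample
mean is the variance-of-the-mean formula Δ = √(Σ(t̄−tᵢ)²/(n(n−1))),
identical to SD/√n; it is implemented from the definition and tested
against the SD/√n identity. Group comparisons are two-sided Welch tests
(scipy, `equal_var=False`) at α = 0.05 with Welch–Satterthwaite degrees of
freedom; both-sides-degenerate samples with equal means report p = 1 by
convention. No multiplicity correction is applied by default, matching the
reported analysis; Bonferroni is available. Cells are pooled within a
sample (the published replicate structure is unstated); the empirical size
of the test stays within [0.03, 0.08] at triplicate sample sizes even at
the 8.5× SD ratio observed between cell lines — the property that
motivates the unequal-variance choice.

For comparisons computed from published summary statistics the per-side
n is 3 (the uptake figures state three measurements).

## Morphometry

Segmentation: global Otsu threshold (objects darker by default), largest
8-connected component, hole filling — scikit-image primitives. Perimeter:
Moore-neighbor boundary trace, length 1 per axial and √2 per diagonal
step. This estimator is fixed so results are reproducible bit-for-bit, and
its bias is documented: on smooth boundaries it overestimates length by
~5%, so an ideal digital disk measures circularity ≈ 0.90 rather than 1.0,
while squares measure π/4 within discretization (+3%). Rank order across
shapes (disk > ellipse > irregular) is preserved, which is what the
circularity comparisons consume. Feret diameter is the maximum pairwise
distance over convex-hull vertices of the boundary (equal to the
brute-force maximum over all boundary pixels, kept as a test oracle); the
equivalent-disk diameter 2√(A/π) is reported as an alternative size
column because the published "diameter" is not unambiguously Feret.
Circularity 4πA/P² is clamped to 1. Growth curves divide each spheroid's
Feret by its own 0 h value (spheroids lacking a 0 h baseline are dropped
with a log entry) and average across spheroids with the Δ uncertainty.

## Ki67 gating

The gating strategy is not published; the package gates at the 99th
percentile of a control sample's Ki67 channel (configurable, or a fixed
threshold). This passes ~1% of true negatives by construction, so a
perfectly separated 30% positive mixture reads ≈ 30.7%. PI is used only to
exclude zero-intensity debris. Positive fraction is the primary readout;
median intensity is emitted as a secondary column since the published
"Ki67 level" could be either. Gating requires ≥500 events.

## Synthetic data

Generators state a world anchored to the published summary values
(`bnctkit.anchors`, asserted verbatim by a test):

- **Uptake**: mean curve `A·(t/4h)·exp(1−t/4h)` through the 4 h anchor
  mean, normal replicate noise with the anchor's relative SD, clipped at
  zero. The 4 h and 6 h means differ by ~9%, so with realistic noise the
  empirical peak lands on 4 h or 6 h — matching the published observation
  that concentrations peak "at 4 h and 6 h".
- **Comet**: per-cell Beta on [0, 100] with the anchor mean and per-cell
  variance `n_cells·SE²`, so the SE of a sample mean matches the anchor;
  infeasible (mean, variance) pairs raise. Freeze–thaw damage is an
  optional additive baseline shift, not a correction.
- **Spheroids**: star-convex disks `r(θ) = R(1 + Σ ε_k cos(kθ+φ_k))`,
  k ∈ {3,4,5,6,8}, amplitudes scaled so the analytic circularity deficit
  `Σ ε_k²(k²−1)/2` hits a target drawn uniformly in the published bands
  (0.87–0.90 irradiated, 0.81–0.84 control). The harmonics are frozen per
  spheroid across time so normalized Feret ratios are exact. Diameter
  growth is exponential at 10%/day, damped by inhibition
  `(0.9 if boron else 0.15)·(1−exp(−dose/2.5))` — a phenomenological
  choice reproducing the qualitative ordering (boron + higher dose →
  stronger inhibition), not a mechanistic survival model. Starting
  diameter 400 µm at 2 µm/px (7-day spheroids; the true value is
  unpublished and the default arbitrary).
- **Flow**: two log-normal Ki67 populations separated in log-intensity,
  single log-normal PI population.
- **ICP-MS**: 5-point linear calibration under the natural-abundance
  convention, constant blank, 10 mg/L QC, multiplicative intensity noise
  (2% default); zero noise makes the quantification round-trip exact.

What a green generator round-trip establishes: the pipeline recovers the
parameters of *this* stated world at the published effect sizes. It does
not establish anything about real images (no illumination gradients,
debris, or out-of-focus halos), real comet distributions (often
zero-inflated or skewed beyond Beta), or real cytometry (no spillover or
autofluorescence structure).

## Numerical choices

- Uptake-peak ties take the earliest time; dose-group tie at 4 Gy takes
  "lower".
- Viability passes strictly above the 95% threshold.
- Welch on two zero-variance samples with equal means: p = 1.
- All generator randomness uses `numpy.random.default_rng(seed)`; a run's
  stage seeds are fixed offsets from the master seed, and bundles contain
  no timestamps, so identical (seed, config) re-runs are byte-identical.
- The full synthetic run uses moderate default sizes (150 cells × 3
  replicates per comet sample, 3 spheroids per arm, 4000 events per flow
  sample) chosen to finish in seconds on one CPU while keeping the
  published effects detectable.

## Limitations

- The 2D planning rows are not reproducible from the published mean
  constants (above); 2D dose predictions from those constants should be
  treated as forward model output, not as a reproduction of the published
  table.
- σ_sys is carried, never computed.
- The chain-code perimeter bias makes absolute circularities ~5–7% lower
  than smooth-boundary estimators (including the generator's analytic
  targets); comparisons between groups measured by the same estimator are
  unaffected.
- The comet replicate structure pools cells within a sample; if true
  replicate-level variance dominates, Δ underestimates the uncertainty.
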