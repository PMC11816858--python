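# bnctkit

Dosimetry and assay statistics for in-vitro boron neutron capture therapy
(BNCT) experiments on melanoma cell cultures and spheroids.

BNCT delivers dose selectively to cells loaded with the ¹⁰B isotope: on
thermal-neutron capture, ¹⁰B(n,α)⁷Li deposits high-LET energy within about
one cell diameter. Benchmarking the therapy in vitro requires a chain of
computations around the irradiation itself, and this package implements
that chain for thermal-column reactor irradiations of 2D cultures and 3D
spheroids:

- **dosimetry** — absorbed dose from the parametrization
  `D_tot = (R_bg + C_B·R_B) · t_irr · P / P_max`, where `R_bg` (mGy/s) is
  the boron-free background dose rate (hydrogen scatter, ¹⁴N(n,p)¹⁴C,
  γ-rays), `R_B` (mGy/(s·ppm)) the dose rate per ppm of ¹⁰B, `C_B` the
  cellular boron concentration, and `P/P_max` the reactor power fraction.
  Includes first-order uncertainty propagation, component decomposition,
  inverse planning (power for a target dose, or time at fixed power), and
  the flux–power conversion.
- **icpms** — ¹⁰B quantification from ICP-MS intensities: OLS calibration
  against a natural-abundance standard (19.9% ¹⁰B), the monoisotopic-sample
  correction (×0.199), blank subtraction, dilution, QC drift check, and
  conversion to ppm and µg ¹⁰B/10⁶ cells; uptake time-course summaries and
  a trypan-blue viability gate.
- **comet_stats** — per-cell %tail-DNA summaries with the
  variance-of-the-mean uncertainty `Δ = √(Σ(t̄−tᵢ)²/(n(n−1)))` (≡ SD/√n)
  and Welch (unequal-variance) t-tests across the experimental arms
  (IR_B / IR / C_B / C).
- **morphometry** — spheroid segmentation (Otsu, largest component, hole
  filling), chain-code perimeter, convex-hull Feret diameter, circularity
  `4πA/P²`, and growth curves normalized to the pre-irradiation diameter.
- **flow_ki67** — Ki67-positive fractions from two-channel flow events via
  a control-quantile gate.
- **synthetic** — seeded generators for every input above, anchored to the
  published summary values (uptake peaking at 4 h, comet means/SEs,
  circularity bands, dose-dependent growth inhibition).

## Worked example

Dose delivered to FM55p spheroids containing 47.5 ppm ¹⁰B, irradiated for
600 s at 12 kW (maximum power 250 kW):

```python
from bnctkit import dosimetry as dm

rates = dm.load_dose_rate_table()[dm.CultureType.spheroid]
boron = dm.BoronMeasurement(C_B=47.5, sigma_C_B=4.6)
plan = dm.IrradiationPlan(P=12)

res = dm.total_dose(rates, boron, plan)
print(f"D_tot = {res.D_tot:.2f} Gy, D_0 = {res.D_0:.2f} Gy, "
      f"sigma_stat = {res.sigma_stat:.2f} Gy")
print({k: round(v, 3) for k, v in res.components.items()})
```

prints

```
D_tot = 2.76 Gy, D_0 = 0.43 Gy, sigma_stat = 0.23 Gy
{'boron': 2.326, 'hydrogen': 0.003, 'nitrogen': 0.123, 'gamma': 0.305}
```

`D_tot` is the dose to the boron-loaded culture, `D_0` the dose to its
boron-free counterpart irradiated with the same fluence; the boron capture
reaction contributes ~84% of the total. `sigma_stat` propagates the
uncertainties of `C_B`, `R_B` and `R_bg` (the boron concentration
dominates).

The full synthetic experiment — dose table, uptake, ICP-MS recovery, comet
comparisons, growth curves and Ki67 summaries — runs from the shell:

```sh
bnctkit all --seed 1 --out run1
```

and is byte-reproducible for a fixed seed and configuration.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the propagated statistical dose uncertainty of the lower-dose
WM266-4 spheroid irradiation plan (17 kW, 600 s, C_B = 36.0 ± 6.8 ppm) by
running the dose pipeline on the bundled dose-rate constants and
irradiation plans, and writes the result as JSON.

## Caveat

The published mean 2D dose-rate constants do not reproduce the published
2D planning-table doses (recomputation gives values ~1.4× larger); the
spheroid rows reproduce within ~1%. The dose report surfaces this as a
warning; verification fixtures assert the spheroid rows only. See
`docs/methods.md`.
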