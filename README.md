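# specbind

Spectroscopic analysis of small-molecule binding to serum proteins.

When a drug binds human or bovine serum albumin it quenches the protein's
intrinsic tryptophan fluorescence, and a handful of classical linear
analyses turn titration spectra into a complete binding characterisation:
affinity, stoichiometry, thermodynamic driving forces, the binding site,
the donor–acceptor distance and the size change of the complex. `specbind`
implements that whole chain as a tested Python library with a thin CLI,
for spectroscopists and pharmacology groups who want the arithmetic of
their binding studies scripted, auditable and reproducible.

## The models

With `F0`/`F` the fluorescence without/with quencher at concentration
`[Q]`:

* **Stern–Volmer**: `F0/F = 1 + Ksv[Q]`; the bimolecular quenching rate
  constant `kq = Ksv/τ0` (τ0 ≈ 10⁻⁹ s for tryptophan). `kq` far above the
  diffusion-controlled limit 2×10¹⁰ M⁻¹s⁻¹, together with `Ksv` falling as
  temperature rises, indicates static quenching (ground-state complex).
* **Double-log binding fit**: `log10(F0/F − 1) = log10 Kb + n·log10[Q]`
  gives the binding constant `Kb` and site number `n`.
* **Thermodynamics**: `ΔG° = −RT ln Kb` per temperature;
  `ln Kb = −ΔH/(RT) + ΔS/R` fitted over temperatures gives ΔH and ΔS
  (R = 1.987 cal mol⁻¹K⁻¹); the ΔH/ΔS sign pattern classifies the dominant
  forces (both negative → hydrogen bonding / van der Waals).
* **Site-marker displacement**: the fractional drop of `Ksv` when
  warfarin/phenylbutazone (Sudlow site I) or diazepam (site II) pre-occupy
  a site names the primary binding site.
* **FRET**: `J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ` by trapezoid quadrature;
  `R0⁶ = 8.79×10⁻²⁵ κ²n⁻⁴φJ` (J in cm³M⁻¹); `E = 1 − F/F0 =
  R0⁶/(R0⁶ + r⁶)`; reliable when `0.5R0 < r < 1.5R0`.
* **Stokes–Einstein**: `Rh = kB·T/(6πηD)`, with a built-in water-viscosity
  table.

A synthetic-data module generates titrations, temperature series, overlap
spectra and displacement sets from a known ground truth, so every
estimator is verifiable end-to-end, and a pipeline runs a whole study from
one YAML config into a unit-labelled JSON report.

## Worked example

```sh
python examples/vant_hoff_thermodynamics.py
```

```
dH = -15.91 kcal/mol   dS = -28.16 cal/mol/K
  T=298 K  Kb=3.14e+05 M^-1  dG=-7.49  TdS=-8.41 kcal/mol
  T=303 K  Kb=2.22e+05 M^-1  dG=-7.41  TdS=-8.50 kcal/mol
  T=310 K  Kb=1.12e+05 M^-1  dG=-7.16  TdS=-8.75 kcal/mol
dominant forces: hydrogen bonding / van der Waals
```

Binding constants of ~3×10⁵ M⁻¹ falling with temperature give ΔG ≈ −7.5
kcal/mol (spontaneous), ΔH ≈ −15.9 kcal/mol (exothermic, complex less
stable when warm) and negative entropy — the signature of hydrogen-bonded,
van der Waals contacts. `TΔS = ΔH − ΔG` is reported alongside ΔS because
published tables sometimes print TΔS (kcal/mol) under a ΔS heading.

The other scripts in `examples/` walk through each capability one at a
time (quenching fits, displacement, FRET distances, hydrodynamic sizing,
and the full simulate→fit→report pipeline); each prints the numbers it
computes and a line on what they mean. The same stages are available from
the shell:

```sh
specbind simulate --out study --seed 1
specbind run --config study/study.yaml --verbose
specbind fit-thermo 298:3.14e5 303:2.22e5 310:1.12e5
```

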