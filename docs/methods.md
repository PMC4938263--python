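# Methods

## Quenching model and estimators

The package treats quenching data in the standard linearised forms. The
Stern–Volmer fit regresses `F0/F` on `[Q]` by ordinary least squares with
a **free intercept**: forcing the intercept to 1 would hide blank
subtraction or inner-filter problems, so instead the intercept is reported
and flagged when it departs from 1 by more than 0.1. `[Q]` is the total
added quencher concentration; no free-ligand correction is applied (the
protein is typically ≤10% of the quencher over most of the titration).
`kq = Ksv/τ0` uses the average integral tryptophan lifetime τ0 = 10⁻⁹ s by
default.

The binding fit regresses `log10(F0/F − 1)` on `log10[Q]` (base-10
throughout this equation — a natural-log reading would change the
intercept→Kb mapping). Points with `F0/F − 1 ≤ 0` have no defined
logarithm; they are dropped deterministically and their indices recorded
in the fit result so the exclusion is auditable. Both fits are plain
closed-form OLS; no nonlinear fit of the untransformed hyperbola is
offered, since the linear-transform estimates are what this class of study
reports and reproduces.

### Mechanism classification

Static quenching is called when Ksv is **strictly decreasing** over the
supplied temperatures and every kq exceeds the diffusion-controlled
collision limit 2.0×10¹⁰ M⁻¹s⁻¹; dynamic when Ksv strictly increases and
no kq exceeds the limit; anything else is ambiguous. With only three
temperatures a regression-slope significance test is not identifiable, so
strict monotonicity is used deliberately.

### Site-marker displacement

For each marker, `fractional_decrease = 1 − Ksv(with marker)/Ksv(free)`.
The marker with the largest decrease names the primary Sudlow site; other
sites whose marker decrease exceeds 0.5 are flagged secondary (that
threshold reproduces the customary reading that a halving of Ksv means the
site "cannot be neglected"). If no marker lowers Ksv the call is "none".

## Thermodynamics

`ΔG° = −RT ln Kb` with R = 1.987 cal mol⁻¹K⁻¹ (configurable, but the
calorie convention is the default because it is what this literature
prints). The van't Hoff fit is **unweighted** OLS of `ln Kb` on `1/T` —
with three temperatures any weighting scheme is unidentifiable — and
assumes ΔH, ΔS temperature-independent over the 12 K span. Results carry
both ΔS (cal mol⁻¹K⁻¹, from the intercept) and per-temperature
`TΔS = ΔH − ΔG` (kcal/mol): published tables in this field sometimes print
TΔS under a ΔS heading, and emitting both removes the ambiguity. Force
classification follows the Ross–Subramanian sign rules with a configurable
|ΔH| ≤ 1 kcal/mol band for "ΔH ≈ 0" (electrostatic).

## FRET

The overlap integral is computed with λ in nm and ε in M⁻¹cm⁻¹, giving J
in nm⁴M⁻¹cm⁻¹, and converted by 10⁻²⁸ to cm³M⁻¹ before the
`R0⁶ = 8.79×10⁻²⁵κ²n⁻⁴φJ` relation (R0 in cm, reported in nm). This is
the only unit dialect under which published J values of order 10¹³ and R0
of order 2 nm are mutually consistent, so both expressions are always
emitted with units attached. Quadrature is composite trapezoid on the
union of the two wavelength grids restricted to the integration range
(default 300–400 nm, configurable); spectra are linearly interpolated and
never extrapolated. Trapezoid was chosen over spline quadrature because
the integrand is smooth and densely sampled and the rule is auditable; on
Gaussian bands it agrees with a 0.01 nm fine-grid quadrature to well below
0.05% at a 1 nm step. Default photophysics: κ² = 2/3 (isotropic), medium
refractive index 1.336, donor quantum yield 0.15 — the standard
tryptophan-donor values. Efficiency from intensities uses the equimolar
donor:acceptor measurement, `E = 1 − F/F0`. Distances are flagged
unreliable outside the strict window `0.5R0 < r < 1.5R0`.

## Hydrodynamics

`Rh = kB·T/(6πηD)` in SI internally, nm at the reporting boundary. The
viscosity of water is user-suppliable or interpolated from a built-in
handbook table (10–40 °C at 1 °C steps). Size-change reports compare each
condition against the flagged ligand-free baseline; direction calls
("compaction" / "expansion/aggregation") require the change to exceed 5%,
below which instrument polydispersity makes calls meaningless. No shape
corrections to the Stokes sphere are applied.

## Spectra handling

Spectrum files are two-column delimited text (comma/tab/whitespace
auto-detected, one optional header line) — the portable common denominator
of instrument exports. Grids must be strictly increasing; duplicate
wavelengths and non-numeric rows are rejected with the offending line
number. Peak maxima are located by argmax and refined by a three-point
parabola through the maximum and its neighbours when the maximum is
interior: without refinement a 1 nm grid quantizes the 2–6 nm shifts that
synchronous scans report. Shifts are signed `λmax(sample) −
λmax(reference)`, negative = blue shift, and the convention is embedded in
every report. "Identical grids" means agreement to 10⁻⁶ nm; resampling
across different grids is linear interpolation on the intersection range,
never extrapolation. Inner-filter correction is not applied.

## Synthetic data

The generator emulates a drug–albumin study: static quenching through the
bound-fraction model (non-fluorescent ground-state complex,
`F = F0/(1 + Kb[Q]^n)`), so the double-log fit inverts it exactly at zero
noise; temperature series with `Kb(T)` from the van't Hoff law; Gaussian
donor/acceptor band pairs whose overlap integral is also evaluated on a
0.01 nm grid as an independent oracle; and displacement sets where each
marker scales the effective quenching constant by a factor in (0, 1].
Defaults are the realistic study conditions: 5 µM protein, 0–50 µM
quencher in 5 µM steps, 298/303/310 K, Kb = 3.14×10⁵ M⁻¹, n = 1.1,
ΔH = −15.806 kcal/mol with ΔS anchored so Kb(298 K) matches, a 14 nm blue
shift of the 340 nm emission band on binding, and 1% multiplicative
Gaussian noise on F (photometric noise; the coefficient of variation is
the parameter). Noise applies to the [Q] = 0 point too, so the reference
F0 carries the same uncertainty as every other reading. Generators are
pure functions of (parameters, seed).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: inner-filter attenuation, photobleaching,
instrument response and wavelength calibration error, free-ligand
depletion at high affinity, non-Gaussian band shapes (real bands are
closer to Gaussian in wavenumber), and correlated drift between titration
points.

### A note on Kb recovery at realistic noise

The double-log estimator is exact at zero noise, and recovers n to ~2%
median error at 1% photometric noise. Kb, however, is the **intercept**
of a line fitted over a single decade of `log10[Q]` centred near −4.7, so
its estimate extrapolates almost five decades: per-point noise — amplified
at low `[Q]` by the factor `(F0/F)/(F0/F − 1)` — propagates to a median
relative Kb error of roughly 20% under the default conditions
(Kb = 10⁵ M⁻¹, 10 titration points, 1% noise). This is a property of the
classical estimator itself, not of the implementation; `log10 Kb` (the
quantity actually fitted) is recovered to ~2%. Studies quoting tight Kb
uncertainties from this plot are implicitly averaging replicates or
quoting the log-scale error.

## Pipeline and report

`run_study` validates that every referenced file exists before computing
anything, then runs the stages in order; any stage may be absent.  Every
numeric field in the report is wrapped as `{"value": x, "unit": "..."}`
and a validator rejects unit-less numbers; the provenance block (config
SHA-256, package version, seed, timestamp) is exempt because its numbers
are identifiers, not measurements. Re-running the same config reproduces
the report byte-identically except for the timestamp. All resolved
constants (τ0, R, κ², φ, refractive index, thresholds) are echoed into the
report so no default is hidden.

## Problem sizes

The test suite and the acceptance script run titrations of 11 points,
three temperatures, 100 noise replicates for recovery statistics, and
overlap integrals on ~150-point grids with a 15 001-point oracle grid —
the sizes of the emulated study itself; the whole suite completes in a few
seconds on one CPU.

## Known limitations

Single-class binding only (no multi-site or cooperative global models);
linear-transform estimates only, with the Kb sensitivity noted above; no
lifetime-based FRET efficiency or κ² estimation; no DLS autocorrelation
fitting (the analysis starts from D or Rh); strict-monotonicity mechanism
calls are brittle when Ksv differences are within noise at adjacent
temperatures.
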