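# Methods

This note records the models implemented in `ionfold`, the assumptions and
defaults behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## The system

A DNA four-way (Holliday) junction equilibrates between an extended open
conformation and a stacked-X conformation with two possible stacking isomers
(isoI, isoII).  Multivalent cations binding at the junction center drive the
open → stacked transition.  The package analyzes three experimental windows
on this process: FRET between dyes on adjacent arms (conformation), ITC
(binding thermodynamics), and lanthanide luminescence (coordination
environment and ion–ion proximity).

## FRET efficiencies and distances

Efficiency is computed by the (ratio)_A method: the acceptor emission band
(570–700 nm by default, configurable) is integrated for the doubly-labeled
sample under donor excitation (F_AD) and under direct acceptor excitation
(F_A), and

    E = (F_AD/F_A − ε_A(dEx)/ε_A(aEx)) · (1/f_D) · (ε_A(aEx)/ε_D(dEx)).

Defaults: ε_A(555) = 89,100 M⁻¹cm⁻¹ (TAMRA), ε_D(494) = 78,000 M⁻¹cm⁻¹
(FAM).  ε_A at the donor excitation wavelength is not a catalogue value; it
must be supplied (or measured as the band ratio of an acceptor-only spectrum
pair) — there is deliberately no hard-coded default other than 0.
(ratio)_A titrations can be divided pointwise by a donor-only intensity
series (relative to its first point) to cancel donor bleaching and
ion-induced quenching; the per-point division is the assumed form of that
correction.

Distances use E = R0⁶/(R0⁶ + R⁶) after dividing the observed efficiency by
the stacked-conformer fraction (default 0.77): the isoI conformer holds the
dyes beyond 2·R0, so it is treated as zero-transfer and only the isoII
population contributes.  Out-of-range efficiencies raise by default; an
explicit `clamp=True` clips noisy values just inside the invertible range.
The Förster radius convention is stated once and unit-tested:
R0⁶ (Å⁶) = 8.79×10⁻⁵ · κ² · n⁻⁴ · Q_D · J, with J in M⁻¹cm⁻¹nm⁴ from
trapezoidal quadrature of F_D(λ)ε_A(λ)λ⁴ on the union of the two wavelength
grids restricted to their common range (donor spectrum area-normalized).
Defaults κ² = 2/3 (isotropic dynamic averaging) and n = 1.4.

The interduplex angle treats the two labeled arms as straight B-DNA
helices, a = b = 17 bp × 3.4 Å/bp = 57.8 Å, and takes the angle opposite
the FRET distance c by the law of cosines.  Dye linkers add roughly 8 Å
offsets that are *not* modeled; the absolute angle therefore carries a
systematic error of a few degrees, and the arm length is exposed as a
parameter rather than tuned.  With these defaults, c = 50–60 Å maps to
≈51°–62°.

## Two-state folding isotherms

Titration signals are fitted to
S(c) = S0 + (Si − S0)·Ka·cⁿ/(1 + Ka·cⁿ) with all four parameters free.
Kd = Ka^(−1/n) is the ion concentration at which open and stacked
populations are equal.  Free-ion concentration is approximated by total
added ion (titrant in large excess over ~50 nM junction).  Numerical
choices: Ka is fitted as log Ka (positivity), n is bounded to [0.3, 4]
(non-cooperative data sits at 1–1.1; the band only guards against runaway
exponents), initial values are the endpoint signals, n = 1, and the best Kd
from a log-spaced scan at 8 points/decade across the sampled range (guards
against local minima).  Weights are 1/sd when per-point uncertainties are
present, otherwise unweighted.  Kd uncertainty is propagated from the
(log Ka, n) covariance by the delta method.  Flat signals raise a
no-transition error rather than returning a degenerate fit.  The same
fitter serves FRET and Tb³⁺ sensitized-luminescence titrations.

## ITC with two classes of independent sites

The cumulative heat content is Q = V[M] Σᵢ nᵢΔHᵢKᵢ[L]/(1 + Kᵢ[L]), with
free ligand [L] the unique root of the mass balance, found by bracketed
Brent iteration on [0, L_tot] to ~1e-12 relative tolerance (the residual is
strictly monotone, so the root always exists and is unique).

Injection bookkeeping uses the standard overfill-cell perfusion model —
after an injection of volume v into cell volume V, both cell concentrations
scale by (1 − v/V) and the ligand gains L_syr·v/V — and per-injection heats
carry the midpoint displaced-volume correction
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (v/V)(Qᵢ + Qᵢ₋₁)/2, matching common instrument-vendor
treatment of the expelled reaction volume.  The cell volume defaults to
1.4 mL (typical of VP-class instruments; configurable).  Concatenated
titration rounds on the same cell contents are a joined injection schedule;
dilution carries across rounds automatically.

Because n₁ΔH₁K₁ and n₂ΔH₂K₂ are strongly interdependent, the two-class fit
holds the class-1 enthalpy and association constant fixed to values obtained
independently from the van't Hoff analysis of temperature-dependent FRET
titrations (ln Ka = −ΔH/(RT) + ΔS/R, ordinary least squares of ln Ka on
1/T; R = 1.9872 cal mol⁻¹K⁻¹).  Free parameters are n₁, n₂ (log-transformed
for positivity), ΔH₂ and log K₂, plus a constant per-injection blank offset
for dilution heats (fitted by default, or supplied).  χ² is reported as the
sum of squared residuals in (µcal)²; comparability with any particular
vendor software's χ² statistic is not claimed — only the ordering between
the one-class and two-class fits is meaningful.  Per-class entropies follow
from ΔG = −RT ln Ka and ΔS = (ΔH − ΔG)/T at the experiment temperature
(283.15 K for the default protocol).

## Lanthanide lifetimes, hydration and LRET

Decays are fitted as A·exp(−t/τ) + b beyond a configurable dead time
(default 2 µs after the pulse), with the baseline seeded from the trace
tail, the lifetime from a log-linear regression, and a Wald–Wolfowitz-style
runs check on the residual signs recorded with each accepted fit.  Only
mono-exponential decays are supported — a single environment is what the
fitted data resolve — and a fitted lifetime longer than half the time
window raises rather than returning an unresolved value.

Hydration numbers use q = A′(1/τ − α′) with the frozen empirical constants
A′ = 1.11 ms and α′ = 0.44 ms⁻¹ (lifetime converted to ms internally;
q = 0 with a warning at or beyond the 2272.7 µs root).  Full-precision q is
always reported; the one-decimal table value is *floored* rather than
round-half, a conservative display convention under which the displayed
water count never overstates the inferred inner-sphere hydration.  Aqueous
Eu³⁺ averages use only the 464.1 and 464.5 nm excitations — the 465.0 nm
lifetime is anomalously long (solution impurities) and is retained in the
table but excluded from the average; averages are computed on lifetimes
first, then converted to q.

LRET efficiencies are E = 1 − τ_DA/τ_D and distances R = R0(1/E − 1)^(1/6)
with R0 = 6.0 Å for the Eu³⁺→Nd³⁺ pair.  The donor-only lifetime defaults
to the junction-bound Eu³⁺ value (124.8 µs) rather than aqueous Eu³⁺; since
free Eu³⁺ (~110 µs) also contributes to the observed decay, the derived
distances may represent an upper limit, and that caveat is attached to
every LRET result.

## Synthetic data: what it does and does not emulate

Each generator draws from exactly the forward model its fitter assumes —
two-state isotherms, the two-class ITC model with perfusion dilution,
mono-exponential decays, Gaussian emission bands, van't Hoff Ka(T) — plus
seeded Gaussian (or Poisson, for counting data) noise.  One documented RNG
(`numpy.random.default_rng`) is seeded per generated dataset.

Preset conditions: Mg²⁺ FRET titration (Kd 22 µM, n 1.05, E0 0.05, Ei 0.35,
σ = 0.01, 20 log-spaced points over 1–1000 µM); ITC truth (n₁ 2.1,
K₁ 40,180 M⁻¹, ΔH₁ −14.9 kcal/mol; n₂ 15.9, K₂ 25,000 M⁻¹,
ΔH₂ +1.9 kcal/mol) with 50 × 10 µL of 0.85 mM titrant into 16 µM junction
and σ = 0.1 µcal; decays at 124.8/74.7 µs with SNR 100; Tb³⁺ composite
titration with a 0.2 µM specific site plus a 10 µM nonspecific component
whose amplitude is calibrated (deterministic noiseless root-find, done once)
so that a single-site fit reports an apparent Kd of 1.2 µM, with noise at
1% of the dynamic range.  The noise scales are conventions consistent with
the relative scatter of typical data of each kind, not measured instrument
parameters.

The generators do **not** emulate instrument physics: no inner-filter
effects, shutter transients, baseline drift, raw ITC power traces,
multi-exponential decay mixtures, or conformer-population changes with ion
type.  Passing the recovery tests therefore demonstrates that the
estimators are unbiased and well-conditioned *under the assumed models and
noise*, not that real instrument artifacts are handled; on real data the
blank correction, donor normalization and dead-time choices matter and are
exposed as configuration.

Stochastic recovery checks report the **median over seeded replicates**
(100 for the acceptance script): a single noisy realization of the Tb³⁺
composite titration has an ill-conditioned apparent Kd (the composite pulls
the fitted Hill coefficient below 1), and the median is the stable summary
of what the estimator recovers.

## Degenerate inputs and tie-breaks

Zero/negative acceptor band integrals, flat titrations, flat spectra,
pure-baseline decays, triangle-inequality violations and out-of-range
efficiencies all raise typed exceptions rather than returning NaN; fits
that do not converge raise with best-so-far parameters attached.  CSV
readers enforce unit-suffixed column names exactly (`conc_M`, never
`conc_uM`) and refuse schema versions newer than they understand.  The full
pipeline report serializes with sorted keys and no timestamps, so a rerun
with the same configuration and seed is byte-identical.

## Problem sizes

Default analysis sizes — 20-point titrations, 50-injection thermograms,
1001-point decays, 100-replicate recovery medians — match the scale of the
corresponding experiments while keeping the whole suite and the acceptance
script fast enough to run routinely.

## Known limitations

- Dye-linker geometry and anisotropy-based distance errors are taken as
  fixed inputs, not modeled; absolute interduplex angles carry that
  systematic.
- The apparent-Kd analysis does not model counterion condensation or ionic
  background competition (e.g. differing Na⁺ levels between titrations).
- ITC blank heats are a constant per-injection offset; drifting baselines
  are out of scope.
- Only two-state (single-transition) isotherms and mono-exponential decays
  are supported; sequential or competitive binding models are not.
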