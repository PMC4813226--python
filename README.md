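# ionfold

Quantitative analysis of metal-ion binding to DNA four-way (Holliday)
junctions, for spectroscopists and nucleic-acid biophysicists who measure
ion-induced junction folding by FRET, isothermal titration calorimetry (ITC)
or lanthanide luminescence.

A four-way junction switches between an extended *open* conformation and a
compact *stacked-X* conformation when multivalent cations bind at its
center.  `ionfold` implements the complete analysis chain that turns raw
titration, calorimetry and luminescence-decay tables into binding constants,
thermodynamic parameters, hydration numbers and inter-ion distances:

- **FRET** (`ionfold.fret_core`) — efficiencies by the (ratio)<sub>A</sub> method,

  *E* = (F<sub>AD</sub>/F<sub>A</sub> − ε<sub>A</sub>(494)/ε<sub>A</sub>(555)) · (1/f<sub>D</sub>) · (ε<sub>A</sub>(555)/ε<sub>D</sub>(494)),

  Förster radii from overlap integrals (R₀⁶ = 8.79×10⁻⁵ κ² n⁻⁴ Q<sub>D</sub> J Å⁶),
  dye–dye distances R = R₀(1/E − 1)^(1/6) after correcting for the stacked-conformer
  population, and interduplex angles by the law of cosines
  c² = a² + b² − 2ab·cosθ.
- **Folding isotherms** (`ionfold.binding_models`) — two-state Hill fits
  E = E₀ + K<sub>a</sub>[M]ⁿ(E<sub>i</sub> − E₀)/(1 + K<sub>a</sub>[M]ⁿ), with
  K<sub>d</sub> = K<sub>a</sub><sup>−1/n</sup>.
- **Calorimetry** (`ionfold.itc_thermo`) — two classes of independent sites,
  Q = V[M] Σᵢ nᵢΔHᵢKᵢ[L]/(1 + Kᵢ[L]), with the free-ligand mass balance
  solved numerically per injection, perfusion dilution of the cell, van't Hoff
  analysis (ΔH = −R·d ln K<sub>a</sub>/d(1/T)) and entropy derivation
  ΔS = (ΔH − ΔG)/T.
- **Lanthanide luminescence** (`ionfold.lanthanide`) — mono-exponential
  lifetime fits, hydration numbers q = A′(1/τ − α′) (A′ = 1.11 ms,
  α′ = 0.44 ms⁻¹), and Eu³⁺→Nd³⁺ LRET distances R = R₀(1/E − 1)^(1/6)
  with E = 1 − τ<sub>DA</sub>/τ<sub>D</sub>.
- **Synthetic data** (`ionfold.synthetic_data`) — seeded generators whose
  forward models are exactly the fitted models, with named presets for the
  study conditions.
- **I/O and orchestration** (`ionfold.io_cli`, `ionfold` CLI) — unit-suffixed
  CSV dialects, TOML run configuration, and a one-command full-pipeline
  report.

## Worked example

Fit a seeded synthetic Mg²⁺ titration (truth K<sub>d</sub> = 22 µM, Gaussian
noise σ = 0.01 on the efficiency):

```python
from ionfold import synthetic_data as sd
from ionfold.binding_models import fit_two_state

series = sd.preset("mg_fret", seed=1)
fit = fit_two_state(series)
print(f"Kd = {fit.kd_apparent*1e6:.1f} uM   Hill n = {fit.hill_n:.2f}   "
      f"E0 = {fit.e0:.3f}  Ei = {fit.ei:.3f}")
```

prints

```
Kd = 21.4 uM   Hill n = 1.08   E0 = 0.054  Ei = 0.346
```

i.e. the apparent dissociation constant is recovered within the noise (21.4
vs 22 µM), binding is non-cooperative (n ≈ 1), and the efficiency baselines
bracket the 0.05 → 0.35 folding transition.  The same quantities are
available from the shell:

```console
$ ionfold hydration --tau-us 124.8
tau = 124.8 us -> q = 8.405831 (table: 8.4)
$ ionfold lret --tau-da 74.7 --tau-d 124.8
E = 0.4014 -> R = 6.41 A (R0 = 6.0 A)
```

The first line converts the junction-bound Eu³⁺ lifetime into ~8 inner-sphere
waters (one fewer than aqueous Eu³⁺, indicating one direct ion–DNA contact);
the second turns the Nd³⁺-quenched lifetime into a 6.4 Å inter-ion distance.
`ionfold report --out report.json` runs every stage on the bundled presets
and emits the full JSON report plus a readable summary.

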