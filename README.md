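# sterolex

Kinetic analysis of protein-mediated sterol extraction from liposomes.

Lipid-transfer proteins of the OSBP/ORP family pull sterols out of
membranes through a lipid-binding barrel, and membrane phosphoinositides
such as PI(3,4)P₂ can allosterically accelerate this extraction. The bench
readout is a FRET assay: a fluorescent sterol (dehydroergosterol, DHE)
excites a dansyl-PE probe embedded in donor liposomes, and the FRET signal
falls as protein removes the sterol. `sterolex` implements the full
quantitative chain for such assays — liposome-composition arithmetic,
signal-to-concentration conversion, the three-step extraction scheme with
its initial-velocity equations, and nonlinear recovery of the kinetic
constants — plus seeded synthetic-data generators so every stage is
testable without instrument data.

## The model

Extraction of one sterol molecule C by a protein O from a cargo-loaded
liposome site L(C) proceeds in three reversible steps:

    O + L(C)  ⇌[k₊₁/k₋₁]  O·L(C)  ⇌[k₊₂/k₋₂]  O(C)·L  ⇌[k₊₃/k₋₃]  O(C) + L

When membrane association/dissociation is fast relative to cargo transfer
(the quasi-equilibrium assumption), the initial velocity of sterol
appearance on protein takes closed forms with K₁ = k₋₁/k₊₁:

* hyperbolic (free protein ≈ total protein):
  `v₀ = k₊₂·[L(C)]₀·[O] / (K₁ + [O])`
* tight-binding quadratic (protein and site pools comparable, free protein
  eliminated exactly):
  `v₀ = (k₊₂/2)·{[O]₀ + [L(C)]₀ + K₁ − √(([O]₀ + [L(C)]₀ + K₁)² − 4·[O]₀·[L(C)]₀)}`

Fitting v₀ against a protein titration recovers the membrane dissociation
constant K₁ (μM) and the extraction rate k₊₂ (s⁻¹); the second-order
efficiency k₊₂/K₁ is the single number compared between basal and
phosphoinositide-stimulated conditions. The full mass-action ODE system is
included as the brute-force oracle for the quasi-equilibrium limits.

## Worked example

```python
import numpy as np
from sterolex import (
    DEFAULT_BASAL, DEFAULT_STIMULATED, NoiseModel,
    generate_velocity_dataset, fit_velocity_model, compare_conditions,
)

basal = fit_velocity_model(
    generate_velocity_dataset(DEFAULT_BASAL, noise=NoiseModel(0.05, 0, 2)))
stim = fit_velocity_model(
    generate_velocity_dataset(DEFAULT_STIMULATED, noise=NoiseModel(0.05, 0, 3)))
print(f"basal: K1 = {basal.K1_hat:.2f} ± {basal.K1_se:.2f} uM, "
      f"k+2 = {basal.k_plus2_hat:.3f} ± {basal.k_plus2_se:.3f} /s")
cmp_ = compare_conditions(basal, stim)
print(f"k+2/K1 fold (stim/basal): {cmp_.second_order_fold:.2f} "
      f"± {cmp_.second_order_fold_se:.2f}")
```

prints

```
basal: K1 = 0.90 ± 0.11 uM, k+2 = 0.052 ± 0.002 /s
k+2/K1 fold (stim/basal): 4.96 ± 0.91
```

— the basal titration (true K₁ = 0.8 μM, k₊₂ = 0.05 s⁻¹, 8 protein
concentrations × 3 replicates at 5% noise) is recovered within its standard
errors, and the stimulated condition (K₁ halved, k₊₂ doubled) shows the
expected ~4-fold gain in second-order extraction efficiency (4.96 ± 0.91
for this draw; the median over many seeded pairs is ≈ 4).

The same pipeline is scriptable from the shell
(`sterolex generate | simulate | convert | v0 | fit | report`), and the
numbered drivers under `analysis/` run the four studies end to end, writing
tables to `results/`:

1. `01_assay_compositions.py` — accessible-lipid pools of the assay recipes
   (10 μM DHE, 4 μM and 3 μM phosphoinositide, 5:1 lipid:protein).
2. `02_oracle_equivalence.py` — mass-action ODE vs the quadratic velocity
   equation over an 18-cell grid (agreement to 0.33%).
3. `03_parameter_recovery.py` — 200-dataset Monte-Carlo recovery of K₁ and
   k₊₂ under both velocity models.
4. `04_condition_comparison.py` — fitted fold changes between conditions
   and the equal-final-extraction plateau check.

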