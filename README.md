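# actinkit

Equilibrium and kinetic models for proteins that regulate actin assembly
through two distinct activities: **sequestering** monomeric G-actin into an
assembly-incompetent 1:1 complex, and **capping** filament barbed ends with
nanomolar affinity. The package grew out of the quantitative analysis of
Eps8-family capping domains, but the models are generic for any WH2-type
monomer binder or barbed-end capper characterized by fluorescence
titrations and seeded elongation assays.

It is written for biochemists who fit these assays routinely: model classes
in the statsmodels style (`Model(...).fit()` → `Results` with estimates,
bootstrap confidence intervals and a `summary()` table), seeded
synthetic-data generators so every estimator can be validated by parameter
recovery, and a small CLI for file-based runs.

## Models

**Ligand-depletion binding isotherm.** When the labelled actin
concentration `A0` is comparable to the dissociation constant, the free
ligand approximation fails. The complex concentration `C` is the physical
root of the mass-action quadratic

    (A0 − C)(L0 − C) = Kd · C ,   0 ≤ C ≤ min(A0, L0)

and the observed fluorescence is `F = F0 + ΔF · C/A0`. Fitted parameters:
`(Kd, F0, ΔF)`.

**Seeded elongation rate law.** Initial filament growth from free ends:
`V = [ends] · k₊ · (C − Cc)` with `k₊ = 10 µM⁻¹s⁻¹` and critical
concentration `Cc` (defaults 0.1 µM barbed, 0.6 µM pointed). Two inhibition
mechanisms act on it:

* *Capping* — the inhibitor binds the ends themselves; normalized rate
  equals the free-end fraction from the end-depletion quadratic
  (`Kcap` in nM, independent of total G-actin);
* *Sequestration* — the inhibitor binds monomer; normalized rate is
  `100·(Afree − Cc)/(A0 − Cc)` with `Afree` from the monomer-depletion
  quadratic (`Kseq` in µM, half-inhibition point scales with `A0`).

That `A0` dependence is the operational discriminator:
`discriminate_mechanism` fits both hypotheses jointly to titrations at two
G-actin concentrations and classifies by residual sum of squares,
reporting "ambiguous" when the two fits are within 5%.

**Competition and two-site equilibria.** Mutually exclusive binders are
solved exactly by bracketed root finding on free actin; the classical
linear correction `K_app = K_T⁰(1 + [E]/K_E)` is kept alongside (and its
inversion cross-checks independently quoted constants). Ligands on
independent sites give additive fluorescence increments.

**Nucleotide exchange.** Observed pseudo-first-order εATP exchange rate
`k_obs = f_b·k_bound + (1−f_b)·k_free` with the bound fraction from the
depletion quadratic; traces are single-exponential rises.

**Helical geometry and amphipathicity.** Filament symmetry arithmetic
(twist `n` subunits/turn ↔ signed rotation `−360/n`°, overlapping-box
segmenting counts), helical-wheel projection at 100°/residue, hydrophobic
moment `µH = |Σᵢ Hᵢ(cos iδ, sin iδ)|`, and the largest contiguous
hydrophobic face.

**Hydrodynamic sizing.** Siegel–Monty `MW = α·a·s` with α calibrated from
standards, linear SEC/gradient calibrations, and prolate axial ratio from
the numerically inverted Perrin frictional function.

## Worked example

Simulate a low-salt fluorescence titration (1.5 µM NBD-actin, true
Kd = 50 nM, 2% noise) and fit it:

```python
import numpy as np
import actinkit.simulate as sim
from actinkit.models import BindingTitration

curve = sim.gen_titration(Kd=0.05, A0=1.5, grid=np.linspace(0, 2, 15),
                          noise=0.02, seed=42)[0]
res = BindingTitration.from_dataframe(curve.to_frame(), A0=1.5).fit(seed=42)
print(res.summary())
```

```
BindingTitration fit (binding-1to1-depletion)
  n_obs = 15, RSS = 13.2613, converged = True
  param             estimate     std err       [2.5%      97.5%]
  Kd               0.0373421      0.0279    0.004859      0.4975
  F0                 100.104      0.2363       99.57       100.4
  dF                 19.4859       1.125       18.05       29.09
```

A single 15-point titration at 2% noise pins the baseline and amplitude
tightly but leaves Kd with a wide bootstrap interval (the transition region
contributes only a few points) — which is exactly why conclusions rest on
the median over many replicates rather than a single curve. The filament
geometry report is analytic:

```
$ actinkit geometry --twist 2.16 --box 80 --overlap 60 --pixel-size 0.54
twist 2.16 subunits/turn -> rotation -166.67 deg (-167 deg nearest)
```

with the JSON report also recording 15.7 subunits per 80-pixel box and 4
overlapping views per asymmetric unit.

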