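# Methods

This note records the models actinkit implements, the numerical choices
behind them, what the synthetic-data generators do and do not emulate, and
the design decisions that were genuinely open.

## Binding equilibria

All concentrations are µM internally; readers convert nM/mM explicitly.
The 1:1 isotherm is solved in its ligand-depletion form because the assays
it models run labelled actin at 1–2 µM against constants from tens of nM to
µM — the free-ligand approximation would bias fitted Kd values low by up to
an order of magnitude in the nM regime. The quadratic root is evaluated in
the conjugate form `2·A0·L0 / (b + √(b² − 4·A0·L0))`, `b = A0+L0+Kd`, which
avoids catastrophic cancellation when `Kd ≪ A0, L0`.

Competition between two mutually exclusive ligands is solved exactly:
substituting the mass-action ratios into actin conservation gives a
residual monotone in free actin, bracketed on `[0, A0]` and solved with
Brent's method to near machine precision; conservation is verified to
relative 1e−9 and violation raises rather than returning silently. The
linear apparent-Kd correction `K_app = K_T⁰(1 + [E]/K_E)` is kept as a
separate function because published competition analyses quote it; its
validity domain (total actin well below both constants, so free competitor
≈ total competitor) is asserted by a test comparing it with an IC50-style
readout of the exact solver at `A0 = 0.01 µM` (agreement within 10%).
Inverting the correction for the competitor's own constant is exposed with
an optional cross-check: when an independently quoted value deviates from
the formula-implied mean by more than 50% relative, the report flags it as
inconsistent rather than averaging it in. Two-ligand systems on
independent sites form the ternary complex freely (no cooperativity): each
site equilibrates through its own depletion solve against total actin and
fluorescence increments add.

## Elongation kinetics

The rate law `V = [ends]·k₊·(C − Cc)` uses `k₊ = 10 µM⁻¹s⁻¹` and is clipped
at zero below the critical concentration. `Cc` defaults to 0.1 µM (barbed)
and 0.6 µM (pointed) — standard Mg-ATP-actin values, configurable per
assay. Capping titrations use the end-depletion quadratic by default
because seeded assays run 2–5 nM free ends against capping constants of
7–100 nM, where depletion is not negligible; the plain hyperbola
`100/(1 + X/Kcap)` remains available for comparison with legend-style
fits. Normalized rates are clipped to [0, 120]% on input (raw control
scatter can overshoot 100) and model rates floored at 0.

Mechanism discrimination fits one shared constant jointly across a pair of
titrations at two G-actin concentrations under each hypothesis and
classifies by lower joint RSS. A relative RSS gap below 5% returns
"ambiguous" — noise should never be converted into a mechanistic claim.
The IC50 shift ratio (high-A0 over low-A0, by linear interpolation at 50%
of control) is reported as corroborating evidence: sequestration moves the
half-inhibition point roughly in proportion to `A0`, capping leaves it
fixed. At the default study conditions (A0 = 2 vs 4 µM, 12-point grids, 2%
range noise) the classifier exceeds 95% accuracy on both mechanisms.

Nucleotide exchange is a two-state mixture: `k_obs` interpolates linearly
in occupancy between the free and bound rates, occupancy again from the
depletion quadratic; traces are single exponentials and their fits recover
`k_obs` to 1e−8 relative on clean data.

## Fitting engine

All estimators share one weighted nonlinear least-squares core:

* weights `1/sd` per point when uncertainties are given, else unweighted;
* multi-start over a log-spaced grid (5 starts spanning 4 decades around
  the data-implied scale — the grid point nearest half-inhibition, or the
  median positive grid value) because binding constants are scale
  parameters with long flat valleys in linear space;
* Levenberg–Marquardt for unbounded problems, trust-region-reflective
  under box constraints, then a short damped Gauss–Newton polish with a
  central-difference Jacobian (step `6e−6·max(|p|, 1e−3)`, the
  cube-root-of-eps compromise) so that linear problems land on the
  normal-equations solution to ≤1e−10 — this is asserted against the
  closed form;
* a Nelder–Mead fallback when every gradient start fails, and a
  convergence error carrying per-start diagnostics when that fails too;
* case-resampling (pairs) bootstrap percentile intervals, warm-started
  from the full-data optimum, with all randomness flowing from one integer
  seed — identical data and seed give bit-identical results.

Parameters pinned at a box constraint are listed in the result so a
bound-active fit is never mistaken for an interior optimum. Flat titration
curves (dynamic range under 5% of control) raise an identifiability error
before fitting is attempted.

## Synthetic data and what recovery tests show

Generators evaluate the exact mechanistic model the paired fitter assumes
and add homoscedastic Gaussian noise with sd expressed as a fraction of the
noiseless curve's dynamic range (default 0.02, matching the scatter of
tight published titrations). A run-level seed fans out to per-replicate
streams via `SeedSequence.spawn`, so replicate sets are reproducible and
mutually independent. Rate-titration controls are pinned to exactly 100%
after noise, as measured rates are normalized to the uninhibited control.

Because generator and fitter share the mechanistic core, noiseless
round-trips (exact to 1e−6 relative, verified for every generator/fitter
pair) check implementation consistency, not model adequacy. The noisy
recovery suite — 200 replicates per constant at 2% noise, median within
±15% of truth — probes estimator bias and variance under realistic scatter.
What none of this shows: robustness to photobleaching, drift,
heteroscedastic detector noise, impurity-driven model misspecification, or
errors in the assumed `A0`/`[ends]`; real-data fits inherit those caveats.

Recovery runs and the acceptance script use 200 replicates of 12–15-point
grids — enough for the median's sampling error to sit well inside the ±15%
band while a full run stays under a minute on one CPU.

## Helix and geometry arithmetic

Helical wheels advance 100°/residue (ideal α-helix), origin at residue 1,
counterclockwise positive; 18 residues close exactly five turns, so a
uniform hydrophobicity profile has µH = 0 to machine precision — asserted
exactly, along with invariance of |µH| under a global angular offset.
Residue classes: D/E negative, K/R/H positive, remainder split by the sign
of the hydrophobicity scale (Eisenberg consensus bundled as the default,
Kyte–Doolittle taken from biopython as the alternative; the two disagree
on W/Y/A-type residues, which is intentional — class follows the chosen
scale). The hydrophobic face is the longest circular run of
hydrophobic-classed residues in angular order, ties broken toward the
smallest start angle.

Filament symmetry uses the signed left-handed convention: rotation
`= −360/twist` degrees per subunit, so 2.16 subunits/turn ↔ −166.67° (the
report prints full precision, a 2-decimal rounding, and the nearest
degree, since published values appear in all three forms) and 2.14 ↔
−168.22° ≈ −168°. Axial rise defaults to 2.75 nm/subunit (canonical
F-actin, configurable). Box segmenting: `views = box/(box − overlap)`,
flagged when fractional; `subunits per box = box·pixel/rise`.

## Hydrodynamics

SEC and gradient calibrations are unweighted OLS lines (marker
uncertainties can be supplied as weights); predictions outside the marker
span are flagged as extrapolation. The Siegel–Monty α is the
origin-constrained weighted LS slope of marker MW against `a·s`, so
consistent standards round-trip exactly. Shape: the Perrin translational
frictional function for a prolate ellipsoid, `f/f0 =
√(1−q²)/(q^{2/3} ln[(1+√(1−q²))/q])` with `q = 1/p`, is inverted by Brent
bisection on `p ∈ [1, 10⁴]`; the anhydrous reference sphere uses partial
specific volume 0.73 mL/g (configurable). Frictional ratios below 1 are
rejected as unphysical.

## Known limitations

* No cooperative/Hill binding, anisotropy/FRET observation models, or
  ionic-strength-dependent Kd prediction — low- and high-salt conditions
  are separate datasets.
* No stochastic filament simulation, nucleation kinetics, or length
  distributions; the rate law is the initial-rate approximation.
* Bootstrap intervals are percentile intervals; for heavily bound-active
  or weakly identified fits they can be asymmetric or degenerate, and the
  wide-interval behaviour (constant far above the sampled range) is the
  intended signal, not a defect.
* Hydration is a single configurable constant; no Lamm-equation analysis.
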