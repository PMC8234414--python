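# Methods

## Force transduction model

The clot contraction sensor is a 4 mm silicon platform suspended from its
frame by sixteen rectangular-section torsion beams, four per side, each side's
pair of beam sets joined by a rigid connection arm of length `C`. A platform
displacement `x` (micrometers, perpendicular to the frame) twists every beam
by `θ = arcsin(x/C) ≈ x/C`.

Per beam, angular Hooke's law `τ = ĸθ` holds with torsion stiffness
`ĸ = GJ/L`, where `G` is the silicon shear modulus, `L` the beam length, and
`J = βab³` the torsional constant of the rectangular section (`a ≥ b`). The
shape factor uses the standard closed-form approximation

    β(a/b) = 1/3 − 0.21 (b/a) (1 − (b/a)⁴/12),

which the test suite checks against the classical infinite-series solution
(agreement better than 0.5% for aspect ratios 1–10). For the production
section (a = 50 µm, b = 10 µm), β = 0.291.

Composing the sixteen beams by the small-angle energy method — arms and
anchors rigid, every beam twisting `x/C` — the stored energy is
`U(x) = 16·½ĸ(x/C)²`, so the platform behaves as a linear spring

    k = 16 ĸ / C²    [N/m],    F = kx.

A unit-consistency note: because N/m × µm = µN, forces are carried in
microNewtons against deflections in micrometers with no conversion factor.
The exact-kinematics force `F = nĸ·arcsin(u)/(C√(1−u²))`, `u = x/C`, is
provided to bound the linearization: at `x/C = 0.01` the relative error is
below 10⁻⁴, and at the full 100 µm stroke with `C ≈ 417 µm` (`u ≈ 0.24`) the
hardware is intentionally operated well inside the linear regime observed in
calibration.

Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| beam `L × a × b` | 680 × 50 × 10 | µm | production geometry |
| shear modulus `G` | 50.9 | GPa | configurable; silicon is anisotropic (≈50–80 GPa by orientation), and the solved arm length absorbs the choice |
| beams | 16 (4 arms × 4) | — | production layout |
| platform half-width | 2000 | µm | arm must fit the 4 mm platform |
| chip `k` | 100 | N/m | nominal production stiffness (5 and 300 N/m variants supported) |
| stroke | 100 | µm | camera field of view; 10,000 µN full scale at 100 N/m |

`ĸ = GJ/L` is the standard torsion stiffness; it is the only form
dimensionally consistent with `τ = ĸθ` and the only one that reproduces a
~100 N/m platform from the production geometry. The inverse design
`C = √(nĸ/k_target)` flags (and warns on) solutions exceeding the platform
half-width; for `k_target = 5 N/m` the arm is ≈1867 µm and still fits.

## Calibration linearity

Linearity of a nanoindenter force-deflection sweep is scored as 100 × R² of
the OLS fit of force on deflection. "Linearity" has no unique definition;
R² is adopted as the default because it is scale-free and monotone in noise,
with a max-residual/full-scale alternative exposed
(`linearity_score(..., metric="max_residual")`). A degenerate series (no
force variation) scores 0; fewer than 3 points is an error enforced at
construction.

## Trace pipeline and estimators

Displacement traces are converted pointwise (`F = kx`), preserving
timestamps. Negative deflections down to −1 µm (thermal drift) are tolerated;
larger negatives are a data-quality error, configurable.

Per-sample summaries:

* **max force** — maximum of the centered moving-average-smoothed series
  (default window 30 s; 0 disables). The camera-derived signal is not
  documented as filtered, so the window is exposed. Taking the maximum of a
  smoothed noisy plateau carries a small positive extreme-value bias
  (≈2.5 × the smoothed noise SD — about +19 µN, i.e. 0.65% of the control
  plateau, at the generator defaults); the test suite bounds it at 1% of the
  plateau.
* **plateau force** — mean of the final 10% of samples. Unbiased for curves
  that have plateaued; this is the statistic used for strict mean-recovery
  checks.
* **lag time / time to half-max** — first crossings of 5% and 50% of the
  realized maximum. The 5% and 10% fractions are conventional choices,
  exposed as arguments. A trace that never develops positive force returns a
  flagged summary with kinetics absent.

Whether an instrument's "max force" means the raw maximum or a plateau
estimate is ambiguous; both are reported and the distinction matters only at
the noise floor.

## Percent-change convention

All condition effects use the asymmetric convention: for treated mean `T`
and control mean `Cm`,

    T ≥ Cm:  +100 (T − Cm) / T        (increase, relative to treated)
    T < Cm:  −100 (Cm − T) / Cm       (decrease, relative to control)

This is non-standard but it is the only convention consistent with both
reported force effects at once (7337 vs 2958 µN → +60%; 922 vs 2958 µN →
−69%), so it is applied uniformly to forces and pMLC ratios, and inverted
exactly (`mean_from_percent_change`) wherever the generators need absolute
levels from reported percent changes. The convention is antisymmetric only
at equality; its sign always matches the direction of effect.

Group summaries report mean with sample SD (n−1) and median with IQR
(linear-interpolation quartiles). A single observation yields SD 0 with an
explicit `sd_defined=False` flag and a warning. No hypothesis tests or
multiple-testing procedures are implemented — none are part of the analysis
being reproduced.

## ELISA and blot normalization

The in-cell ELISA ratio is `(mean OD_pMLC − blank) / (mean OD_totalMLC −
blank)` with the blank estimated from dedicated blank wells (0 if absent).
The ratio is invariant under a uniform plate gain and errs explicitly when
either signal fails to exceed the blank. Percent changes are computed on
these ratios rather than raw pMLC OD — the ratio cancels seeding density and
gain, which raw OD does not. Wells aggregate by mean (plates here carry few
replicate wells). Blot lanes are quantified as pMLC over β-actin (stated
loading control), with total-MLC normalization as an option.

## Signaling network

The cascade is a 20-node, 21-edge signed digraph. Kinase arm: Ras → RAF-1 →
MEK → ERK → MLCK → pMLC (all +), with Ca-calmodulin → MLCK (+) and
PKC → ERK (+) (the feedback is encoded as a static forward edge — no cyclic
dynamics). Phosphatase arm: CPI-17 ⊣ MLCP and ROCK ⊣ MLCP, with
PKC → CPI-17 (+), RhoA → ROCK (+), RAF-1/TNFα → RhoA (+), and MLCP ⊣ pMLC.
PKG arm: PKG ⊣ PKC, with NO → PKG (+), PDE5 ⊣ PKG (PDE5 degrades the cGMP
pool sustaining PKG), and the endothelial chain PGI2 → cAMP → PKA → PDE5
encoded so PGI2 is a net negative effector of PKG — the sub-chain's sign
order is the one fully consistent with the explicit sildenafil mechanism
(PDE5 inhibition → more cGMP/PKG → less PKC → more MLCP → less pMLC); the
intermediate signs are the least certain part of the encoding and are
confined to that branch.

Prediction is exhaustive simple-path sign propagation (the graph has ≤20
nodes, so enumeration is exact and cheap; a brute-force DFS oracle in the
tests cross-checks the networkx-based implementation). Flipping a
perturbation's mode flips every non-ambiguous prediction. With the default
reagent bindings, 7 of 8 predictions match observation; sildenafil is
predicted "down" but observed "up" — the model deliberately encodes the
canonical pathway and therefore reproduces the paradox rather than the
observation. Proposed resolutions (fibrinogen depletion, ATP-driven
secondary activation, pMLC-force uncoupling) are outside the static sign
model's scope.

## Synthetic-data generator

The generator emulates the study's data-generating conditions, not clot
biophysics:

* **Traces**: `x(t) = (F∞/k)·[σ((t−t½)/τ) − σ(−t½/τ)]/[1 − σ(−t½/τ)] + ε`,
  σ the logistic function — a sigmoid rebased to start at zero deflection.
  Defaults `t½ = 900 s`, `τ = 300 s`, ε Gaussian with SD 0.2 µm, sampled
  every 5 s for 3600 s. The rebasing means the curve crosses half its
  realized maximum slightly after `t½` (≈928 s at defaults); the kinetics
  tests use the closed-form crossing. Per-subject plateau forces are drawn
  from Normal(mean, SD) truncated at 0. Only the plateau varies across
  subjects — whether real subjects also share kinetics is unknowable from
  group summaries.
* **Condition table**: control 2958 ± 373 µN and the two conditions with
  reported absolute values (U46619 7337 ± 1408, Cpd7a 922 ± 504) are taken
  directly; the remaining six means are back-computed from their reported
  force percent changes through the convention above, and their unreported
  SDs are set once to the control coefficient of variation (12.6%). Zero
  truncation shifts the population mean upward for high-CV conditions
  (Cpd7a: 961 vs 922 µN); recovery checks therefore target the
  truncated-normal mean, which is what the generator actually samples.
* **Calibration**: evenly spaced deflections over the stroke, Gaussian force
  noise defaulting to 4% of full scale — chosen so the linearity score of a
  50-point sweep concentrates near 98% and stays inside the reported 96–99%
  band for all three chip stiffnesses (the fraction is relative, so the band
  is stiffness-independent).
* **ELISA plates**: per-condition signal ODs scaled so the zero-noise
  normalized ratio realizes the configured pMLC effect exactly (control
  ratio 1.0); multiplicative lognormal well noise with unit mean (default
  CV 5%, 8 wells per analyte-condition; blank OD 0.08).
* **Correlation datasets**: condition-level (force, pMLC) points built as a
  fitted line plus residuals orthogonalized against the regressors and
  scaled so the sample R² equals the target exactly — the reported
  force–pMLC R² of 0.91 is defined on unpublished per-volunteer averages,
  so the generator reproduces the statistical structure, not the data.

What passing tests therefore show: the pipeline is an internally consistent,
calibrated chain from geometry to reported statistics under the stated
noise model. What they do not show: anything about fibrin viscoelasticity,
platelet count effects, inter-subject kinetic variability, plate-position
(edge) effects, or instrument drift — none of which the generator emulates.

## Numerical and design notes

* Problem sizes: recovery checks run 1000 subjects per condition (SE of the
  control mean 11.8 µN), calibration checks 100–200 seeds, ELISA direction
  checks 500 seeds; the full suite and the acceptance script each complete
  in seconds.
* All generators accept either an integer seed or a numpy `Generator`;
  identical seeds give bit-identical outputs. The acceptance script derives
  independent sub-streams per quantity from its single seed.
* Geometry constructors normalize `a ≥ b`, reject non-positive dimensions;
  over-stroke deflections warn rather than error (calibration hardware can
  overshoot); arm-length solutions exceeding the platform flag and warn.
* Ties and degenerate inputs: first-crossing kinetics resolve plateaus to
  the earliest sample; zero-variance calibration force scores 0; identical
  ELISA conditions give exactly 0% change.

## Known limitations

* The arm length and silicon orientation of the physical chip are not
  published; "approximately 100 N/m" is under-determined, and the solved
  `C ≈ 417.7 µm` is conditional on `G = 50.9 GPa`.
* The static sign network cannot express dose, kinetics, or the sildenafil
  off-pathway effects; calcium's dual role (Ca-calmodulin and RhoA) would
  require a two-target perturbation, which the binding table supports but no
  default reagent exercises.
* Back-computed condition means inherit the percent-change convention; under
  a different convention the six unreported means would shift.
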