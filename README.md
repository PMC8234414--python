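# clotforce

Analysis toolkit for MEMS-based measurement of platelet clot contraction
force and its relationship to myosin light chain (MLC) phosphorylation.

Platelets contract a forming blood clot through actomyosin cycling, gated by
phosphorylation of the myosin regulatory light chain (pMLC) — the balance of
myosin light chain kinase (MLCK) and phosphatase (MLCP). A silicon
clot-contraction sensor (CCS) measures that force directly: the clot pulls a
platform suspended on sixteen rectangular torsion beams, and a camera tracks
the platform deflection `x`, which Hooke's law converts to force, `F = kx`.
`clotforce` implements the full computational chain around this assay:

* **Torsion-beam mechanics** (`clotforce.mems`) — from beam geometry
  (length `L`, thickness `a`, width `b`), silicon shear modulus `G` and
  connection-arm length `C` to the platform spring constant. For a
  rectangular section the torsional constant is `J = βab³` with
  `β = 1/3 − 0.21(b/a)(1 − (b/a)⁴/12)`; each beam has torsion stiffness
  `ĸ = GJ/L`, and the 16-beam small-angle composition gives `k = 16ĸ/C²`.
  The production beam (680 × 50 × 10 µm, β = 0.291) with `C ≈ 417 µm`
  yields the nominal 100 N/m chip (10,000 µN at its 100 µm stroke).
  Nanoindenter calibration series are scored for linearity as 100 × R².
* **Contraction traces** (`clotforce.traces`) — displacement-to-force
  conversion over the one-hour assay and per-sample summaries: smoothed
  maximum force, plateau force, lag time, time to half-maximum.
* **Statistics** (`clotforce.stats`) — group summaries (mean ± SD,
  median/IQR), the study's asymmetric percent-change convention (increases
  relative to the treated mean, decreases relative to control), and the OLS
  regression of condition-mean pMLC on condition-mean force.
* **Phospho-assays** (`clotforce.phospho`) — in-cell ELISA normalization
  (blank-subtracted pMLC/total-MLC ratio of well means) and Western-blot
  lane ratios against the β-actin loading control.
* **Signaling network** (`clotforce.network`) — the MLCK/MLCP cascade as a
  signed directed graph; static sign propagation predicts the direction of
  pMLC change for each reagent perturbation. Seven of the eight assayed
  reagents are concordant with observation; sildenafil (a PDE5 inhibitor
  predicted to lower pMLC) is the documented paradoxical mismatch.
* **Synthetic data** (`clotforce.synth`) — generators for every input:
  logistic contraction traces with condition-specific plateau forces
  (control 2958 ± 373 µN; U46619 7337 ± 1408; Cpd7a 922 ± 504; the others
  back-computed from their reported percent changes), calibration sweeps
  whose linearity lands in the 96–99% band, ELISA plates realizing each
  condition's pMLC effect exactly at zero noise, and condition-level
  correlation datasets with an exact target R².

## Worked example

Size a chip, simulate a nine-condition study (5 subjects per condition, the
assayed group size), analyze it, and check the network predictions:

```sh
clotforce design --target-k 100
```

```yaml
derived:
  beta_factor: 0.2913389333333333
  torsional_constant_J_m4: 1.456694666666666e-20
  beam_torsion_stiffness_Nm_per_rad: 1.0903788019607838e-06
  spring_constant_k_N_per_m: 100.0
  full_scale_force_uN: 10000.0
solved:
  arm_length_C_um: 417.68481934794494
  fits_platform: true
```

The report says a 417.7 µm connection arm gives the 680 × 50 × 10 µm beams
(shape factor 0.291, per-beam stiffness 1.09 µN·m/rad) exactly the target
100 N/m platform spring constant — 10,000 µN at full stroke.

```sh
clotforce simulate --seed 42 --n-subjects 5 --out traces.csv
clotforce analyze --traces traces.csv --out summary.csv
```

```text
   condition  n        mean          sd      median         iqr  pct_change_vs_control
     control  5 3040.134934  352.148705 3165.520134  332.535735               0.000000
      U46619  5 6077.935738 1194.836679 6609.812170 2080.261013              49.980798
       Cpd7a  5 1333.264647  837.659842 1005.263499  496.909164             -56.144557
  sildenafil  5 4985.719502  752.164676 4860.254270  217.488639              39.023145
         PMA  5 5079.871944  510.510983 5053.474983  387.191624              40.153316
okadaic_acid  5 5726.140174  555.817683 5881.671696  102.834698              46.907780
        ML-7  5 1312.417989  170.758870 1233.401466  223.007709             -56.830272
       K252d  5 1177.539740  182.756556 1210.693340  290.887750             -61.266859
      Y27632  5 1099.276983  154.173340 1097.570638  168.479115             -63.841178
```

Each row is one condition's maximum contraction forces (µN) across the five
simulated subjects; at n = 5 the recovered percent changes scatter around the
configured effects (e.g. U46619 +50% here versus +60% in expectation), just
as small volunteer groups do.

```sh
clotforce predict-direction --compare
```

```text
     reagent target     mode predicted observed  match
      U46619    ERK activate        up       up   True
         PMA    PKC activate        up       up   True
okadaic_acid   MLCP  inhibit        up       up   True
  sildenafil   PDE5  inhibit      down       up  False
       Cpd7a   PDE5  inhibit      down     down   True
        ML-7   MLCK  inhibit      down     down   True
       K252d    PKC  inhibit      down     down   True
      Y27632   ROCK  inhibit      down     down   True
concordant: 7/8
```

## Documentation

`docs/methods.md` describes the mechanical model, the estimators and their
numerical behavior, the percent-change convention, the network encoding, and
exactly what the synthetic generators do and do not emulate about real blood
samples.
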