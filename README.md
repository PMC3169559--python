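# lipidorder

Solid-state ²H and ³¹P NMR lineshape analysis for multilamellar lipid
vesicles — forward simulation of axially symmetric powder patterns,
de-Pakeing deconvolution, acyl-chain order-parameter extraction, and
iterative multi-component ³¹P chemical-shielding-anisotropy fitting.

## Who this is for

Membrane biophysicists characterising the core rigidity and head-group
dynamics of model membranes — in particular complex, phosphoinositide-rich
mixtures such as nuclear-envelope precursor vesicles (MV1-, MV2- and
NER-like compositions of POPC, cholesterol, PtdIns, PtdInsP and PtdInsP₂).
Multilamellar vesicles expose every bilayer orientation to the field, so
each anisotropic interaction yields a "powder" lineshape; quantitative
answers require either deconvolving those shapes into oriented-like
spectra or simulating them outright. This package does both, plus a
seeded synthetic-data generator so every stage is testable without
instrument data.

## The model

**²H quadrupolar patterns.** Each inequivalent deuteron group of a
perdeuterated palmitoyl chain (15 groups: CD₂ at carbons k = 2…15, CD₃ at
k = 16) contributes a Pake doublet with per-orientation splitting
Δν_Q(θ) = 2·Δν_Q(90°)·P₂(cos θ). The 90°-edge splitting maps linearly to
the carbon–deuterium bond order parameter through the static quadrupolar
coupling constant A_Q = 167 kHz:

    Δν_Q(90°) = (3/4) · A_Q · |S_CD|

Plateau positions (k = 2 to 8–10) have their mean C–D bond at 90° to the
long molecular axis, so the headline quantity is 2|S_CD| ∈ [0, 1]: 0 is a
fully disordered fluid, 1 a rigid, fully ordered chain. The terminal
methyl rotates fast about the chain axis (|P₂(cos 109.47°)| = 1/3); its
chain-axis order is the raw mapping × 3.

**³¹P CSA patterns.** Each distinct phosphate environment contributes an
axially symmetric powder pattern with ν(θ) = δ_iso + (2Δσ/3)·P₂(cos θ),
Δσ = σ∥ − σ⊥: intense perpendicular edge at δ_iso − Δσ/3, weak parallel
edge at δ_iso + 2Δσ/3, breadth |Δσ|. PtdInsP₂ alone carries three
environments (glycerol phosphodiester plus the 4- and 5-monoesters), so
an NER-like mixture superimposes seven patterns. Field-induced prolate
deformation of the vesicles is modelled as
w(θ) ∝ sin θ·(1 + ε·(1 − 3cos²θ)/2), which depletes the parallel edge.

**De-Pakeing** discretises the forward powder operator on a grid of
candidate splittings (²H) or candidate anisotropies (³¹P) and solves a
non-negative, Tikhonov-regularised least-squares inversion, collapsing
each doublet to a sharp symmetric pair whose separation is read off
directly.

**³¹P fitting** is statsmodels-style: `P31Model(spectrum, config).fit()`
returns a `P31FitResult` with estimates, standard errors, a residual
norm and `summary()`. Parameters can be frozen, bounded or tied
(the glycerol-bound phosphates of the three phosphoinositides are tied
by default); weights default to frozen stoichiometric values; a
residual-resampling bootstrap provides intervals.

## Worked example

Generate a synthetic NER-like scenario (seeded), run the ²H route
(de-Pake → measure splittings → order profile → thermal table) and fit
the ³¹P spectrum:

```python
from lipidorder import (ScenarioSpec, generate_scenario, depake, DepakeConfig,
                        measure_splittings, assemble_order_profile, thermal_table,
                        FitConfig, P31Model, composition, p31_param_table,
                        composition_to_phosphorus_components)

spec = ScenarioSpec(name="NER", temperatures=(0.0, 10.0, 20.0), seed=7)
spectra, truth = generate_scenario(spec)

profiles = []
for T in (0.0, 10.0, 20.0):
    oriented = depake(spectra[f"2H_T{T:g}"], DepakeConfig(regularization=1e-2))
    measured = measure_splittings(oriented, n_expected=7)
    profiles.append(assemble_order_profile(measured.splittings, T, label="NER"))
print(thermal_table(profiles).to_string(index=False))
```

```
composition  temperature_c  plateau_splitting_khz  splitting_err_khz  plateau_two_s_cd  two_s_cd_err
        NER            0.0              46.667021                1.0          0.745182      0.015968
        NER           10.0              45.641372                1.0          0.728804      0.015968
        NER           20.0              44.729684                1.0          0.714246      0.015968
```

The plateau 2|S_CD| of 0.73 at 10 °C (±0.016 from the ±1 kHz splitting
accuracy) says the NER-like membrane is liquid-ordered — stiffer than
pure POPC (0.47) but softer than POPC/Chol (0.81): the phosphoinositides
partially counterbalance cholesterol's ordering.

```python
components = composition_to_phosphorus_components(composition("NER"),
                                                  p31_param_table("NER"))
result = P31Model(spectra["31P_T10"],
                  FitConfig(components=tuple(components), lb=100.0)).fit()
print(result.summary())
```

```
31P multi-component CSA fit
  components: 7   epsilon: 0.000
  residual norm: 0.02345   iterations: 10   converged: True

  parameter                              value     std err
  delta_sigma[PI_g=PIP_g=PIP2_g]        -55.97      0.0631
  delta_sigma[PC]                       -35.21      0.0423
  delta_sigma[PIP_4]                    -11.46       0.107
  delta_sigma[PIP2_4]                   -11.47       0.105
  delta_sigma[PIP2_5]                   -3.004      0.0171
  ...
```

The seven-pattern fit recovers the POPC anisotropy (−35.2 ppm), the tied
glycerol-bound phosphoinositide anisotropy (−56.0 ppm) and the small
inositol-ring monoester anisotropies (−11.5 and −3.0 ppm) from the noisy
superposition. The near-zero 5-phosphate Δσ corresponds to a tensor axis
close to the magic angle (54.7°), where the effective anisotropy
vanishes.

The same chains run from the shell:

```bash
lipidorder scenario --name NER --temps -5,0,10,20 --seed 42 --out run/
lipidorder depake --in run/2H_T10.txt --reg auto --out run/depaked.txt
lipidorder order-profile run/depaked.txt --out run/profile.csv
lipidorder fit31p --in run/31P_T10.txt --composition NER --lb 100 --out run/fit
lipidorder pipeline --config pipeline.yaml --out run/   # config-driven chain
```

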