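# Methods

## Spectra and conventions

A spectrum is a 1-D frequency-domain trace with a strictly increasing
axis: kHz offset from the carrier for ²H (the carrier sits at the centre
of the symmetric Pake pattern, so 0 kHz is the symmetry point), ppm
relative to 85% H₃PO₄ for ³¹P. Conversion between the two
(ppm × spectrometer MHz / 1000 = kHz) is always explicit, never implicit.
On disk: two-column UTF-8 text ('#' comments, 17 significant digits, so
write∘read is bit-faithful for doubles) plus a JSON sidecar carrying
nucleus, spectrometer frequency, axis kind, temperature and label. ppm
axes are displayed decreasing left-to-right but always stored increasing;
that inversion lives only in the plotting layer.

Two conventions pin every number in the package:

* **Quadrupolar:** the doublet splitting between the intense 90° edges is
  Δν_Q(90°) = (3/4)·A_Q·|S_CD| with A_Q = 167 kHz; per orientation,
  Δν_Q(θ) = 2·Δν_Q(90°)·P₂(cos θ), so the outer (0°) shoulders sit at
  twice the edge splitting. The rigid bound is (3/4)·167 = 125.25 kHz.
* **CSA:** Δσ = σ∥ − σ⊥, per-orientation shift
  ν(θ) = δ_iso + (2Δσ/3)·P₂(cos θ); intense perpendicular edge at
  δ_iso − Δσ/3, weak parallel edge at δ_iso + 2Δσ/3, breadth |Δσ|; the
  first moment of the unbroadened pattern is δ_iso.

## Powder integration

Orientations θ ∈ [0°, 90°] are discretised as midpoints of ≥ 2048 equal-θ
bins. The sphere weight is sin θ; prolate field deformation uses the
single-parameter family w(θ) ∝ sin θ·(1 + ε·(1 − 3cos²θ)/2), truncated at
zero and renormalised. ε = 0 recovers the sphere exactly and any ε > 0
strictly depletes the θ = 0 (parallel-edge) intensity, which is the
qualitative signature the deformation must reproduce; the exact weighting
family is otherwise a package choice, since only that contract is
physically constrained here.

Each orientation's line is deposited onto the axis grid by linear
splitting between the two bracketing grid points, so every sub-spectrum
integrates exactly to its component weight and the singular edges carry
no binning artifacts at the grid scale. Grids that do not cover the
pattern (±1.2 × splitting for ²H; the two CSA edges plus a 2% margin) are
rejected rather than silently truncated.

Lorentzian broadening is circular FFT convolution with a unit-sum
discrete kernel of the requested FWHM. Circular convolution conserves the
total integral exactly (the conservation contract is ≤ 0.1%); the cost is
that far Lorentzian tails wrap around the grid ends, which is negligible
whenever the grid margin exceeds ~10 line widths — the default grids keep
a ≥ 20% relative margin. Non-uniform grids are rejected.

Each component carries an intrinsic line width applied to its own
sub-spectrum; `compose` then applies the instrumental broadening to the
weighted sum (two Lorentzians convolve to a Lorentzian of summed widths).

## De-Pakeing

The powder operator is discretised as a matrix: one column per candidate
component, built with the spherical distribution and broadened to the
configured kernel line width. For ²H the candidates are 90°-edge
splittings (2× the positive axis points up to half the axis maximum, so
every pattern stays on-grid); the spectrum is symmetrised first by
default (quadrupolar spectra are theoretically even; the normalised L1
distance between halves is reported as an asymmetry score, defined so a
one-sided spike of 5% area scores 0.05). For ³¹P the candidates are
anisotropies sharing the spectrum's first moment as isotropic shift — a
deliberate approximation, adequate for initial guesses because the
isotropic shifts here are small against the large anisotropies.

The inversion is non-negative Tikhonov-regularised least squares
(`nnls` on the augmented system); non-negativity is what produces sharp
lines. The regularisation strength is either supplied or chosen by an
L-curve-style heuristic over a fixed geometric grid (1e-4…1e-1, fallback
1e-3), and is recorded in the output metadata together with the
normalised L1 re-projection error of the solution through the forward
matrix. The oriented trace is presented at the kernel line width so
solution mass split across adjacent columns reads as one line. Setting
the kernel line width close to the data's actual broadening matters: a
large mismatch pushes misfit intensity into low-prominence satellite
lines (they stay an order of magnitude below genuine peaks in the tested
regimes, which is why peak detection defaults to a 4%-of-maximum
prominence threshold).

Round-trip behaviour on simulated data (line broadening ≤ 300 Hz):
recovered splittings within 2%, re-projection L1 < 3%, output integral
within 2%, output non-negative by construction.

## Order parameters

Peak pairs in the oriented trace are matched across zero within a
tolerance of max(0.5 kHz, 3 grid steps); a line at |ν| below the
tolerance is reported as an isotropic contaminant, not a splitting.
Assignment follows the standard profile shape: the largest (merged)
splitting is the plateau (k = 2–10 treated as one group), the smallest is
the terminal methyl (k = 16), intermediates fill k = 11…15 in descending
order; degenerate inputs yield partial profiles carrying flags rather
than errors. The methyl entry reports both the raw mapping and the
×3-corrected chain-axis value. The splitting measurement accuracy of
±1 kHz propagates linearly to ±0.016 on the 2|S_CD| scale and is carried
through the thermal tables.

## ³¹P fitting

`P31Model` wraps the forward simulator in bounded damped least squares
(`scipy.optimize.least_squares`, trust-region reflective; relative
tolerance 1e-8, iteration cap 500, optional seeded multi-starts from 10%
jittered initial guesses). Free parameters default to Δσ and δ_iso per
component; line widths and weights are frozen — weights to the
stoichiometric values implied by the composition (mol% per phosphate,
cholesterol contributing none) — and any parameter can be tied across
components. The glycerol-bound phosphates of PtdIns/PtdInsP/PtdInsP₂ are
tied by default: their anisotropies are not separable in practice, and
the recovered tables treat them as one environment. Standard errors come
from the Gauss–Newton covariance at the optimum; a residual-resampling
bootstrap (estimate ± 1.96 bootstrap SE, deterministic per seed, ≥ 10
replicates) provides intervals that by construction contain the point
estimate. On 1%-noise simulations of the shipped compositions, recovered
anisotropies land within ~10% for |Δσ| ≥ 30 ppm and well within 50% for
the small inositol-ring monoesters, matching the accuracy one can claim
for such fits.

## Synthetic data

The generator contains no physics of its own: every trace is the forward
model evaluated on a machine-readable ground truth, plus i.i.d. Gaussian
noise (σ relative to the maximum intensity, default 1%). Scenario
defaults:

* Plateau 2|S_CD| at 10 °C per composition, anchored to the measured
  values where available (0.47 POPC, 0.81 POPC/Chol, 0.69 POPC/Chol/PI,
  0.73 NER-like); remaining compositions are synthetic defaults chosen to
  respect the observed ordering (cholesterol orders, PtdIns disorders,
  MV1-like ≈ POPC/PI, NER-like between POPC/Chol/PI and POPC/Chol).
  Linear temperature trends: −0.005/°C for fluid, −0.0015/°C for
  cholesterol-rich (quasi-constant liquid-ordered) systems.
* Mid-chain splittings relative to the plateau (0.92, 0.82, 0.70, 0.56,
  0.42 for k = 11…15; 0.12 for the methyl) are synthetic defaults giving
  a realistic smoothly decreasing profile — they are not measured values.
* Gel/fluid coexistence near T_m ≈ −5 °C is a convex combination whose
  gel part is the fluid chain profile rescaled so its plateau sits at
  120 kHz (4× broader lines). This keeps both the broad envelope and a
  central gel methyl doublet, so at gel fraction 0.5 the two phases show
  central doublets of equal integrated intensity. It is an admitted
  axially *symmetric* approximation of the true axially asymmetric
  solid-ordered lineshape, for which no quantitative model is pinned
  here.
* A sharp isotropic contaminant (default 3%, zero-anisotropy component)
  is added to ²H spectra; ³¹P spectra are generated clean so their
  stoichiometric weights remain exact.
* ³¹P parameters come from the shipped per-composition anisotropy table;
  compositions without a fitted row fall back to generic per-environment
  defaults. The PE and PS isotropic shifts (0.0 ppm) and all intrinsic
  line widths (100 Hz ³¹P, within the 50–300 Hz processing range) are
  synthetic defaults, not measured values.

Everything is deterministic per seed, including output bytes.

Passing the pipeline tests on these scenarios demonstrates that the
analysis chain is self-consistent and recovers known ground truth through
realistic noise, broadening and contaminants. It does not validate the
gel-phase lineshape model, vendor time-domain artifacts (phasing, drift —
deliberately out of scope), or the true per-position splittings of any
real membrane.

## Numerical choices and limitations

* Problem sizes: 2048-point grids, 2048 orientation bins (1024 inside the
  fit loop and de-Pake kernel), 256-bin comparison grids against ≥ 10⁶
  orientation brute-force histograms. These keep each check to seconds
  while the discretisation error stays an order below every stated
  tolerance.
* Integrals use the rectangle rule (sum × step) on uniform grids
  throughout; the deposition and kernels are defined with the same
  convention, so conservation statements are exact rather than
  quadrature-limited.
* Only axially symmetric tensors are modelled (η = 0); hexagonal, cubic
  and micellar lineshapes are out of scope.
* The ³¹P de-Pake assumes a common isotropic shift (the first moment);
  with environments several ppm apart the resulting candidates are
  starting values, to be refined by the fit, not measurements.
* Peak detection on oriented traces is prominence-based; heavily
  overlapping doublets (closer than the presented line width) merge, and
  the profile assignment then reports fewer positions with a flag.
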