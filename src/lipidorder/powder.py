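"""Forward simulation of axially symmetric powder patterns.

Multilamellar vesicles expose every membrane orientation to the magnetic
field, so each anisotropic interaction produces a powder lineshape: the
orientation-dependent frequency, weighted by the orientation
distribution, accumulated onto a frequency grid.

Conventions (fixed throughout the package)
------------------------------------------
* ²H quadrupolar doublet: per-orientation lines at ±Δν_Q(θ)/2 with
  Δν_Q(θ) = 2·Δν_Q(90°)·P₂(cos θ).  ``splitting_90`` is the separation of
  the intense 90°-edge horns; the outer (0°) shoulders sit at twice that.
* ³¹P axially symmetric shielding: ν(θ) = δ_iso + (2Δσ/3)·P₂(cos θ) with
  Δσ = σ∥ − σ⊥, so the intense perpendicular edge is at δ_iso − Δσ/3 and
  the weak parallel edge at δ_iso + 2Δσ/3; total breadth |Δσ|.
* Orientation distribution of a sphere is sin θ; field-induced prolate
  deformation is modelled as w(θ) ∝ sin θ · (1 + ε·(1 − 3cos²θ)/2),
  truncated at zero, which depletes the θ = 0 (high-frequency) edge.

Intensities are deposited by linear splitting between the two axis points
bracketing each orientation's frequency, so the integral of every
sub-spectrum equals the component weight exactly.  Lorentzian broadening
is a circular FFT convolution with a unit-sum kernel and therefore also
conserves the integral exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositions import (
    A_Q_KHZ,
    RIGID_SPLITTING_KHZ,
    MembraneComposition,
)
from .spectra_io import AXIS_KHZ, AXIS_PPM, Spectrum

__all__ = [
    "QuadComponent",
    "CSAComponent",
    "OrientationDistribution",
    "orientation_weights",
    "quad_powder_subspectrum",
    "csa_powder_subspectrum",
    "effective_delta_sigma",
    "apply_lorentzian_broadening",
    "composition_to_phosphorus_components",
    "chain_to_quad_components",
    "compose",
    "uniform_axis",
    "quad_axis",
    "csa_axis",
]

#: default Larmor frequencies, MHz (9.4 T magnet)
DEFAULT_FREQ_2H_MHZ = 76.0
DEFAULT_FREQ_31P_MHZ = 162.0


@dataclass(frozen=True)
class QuadComponent:
    """One deuteron group: 90°-edge splitting, abundance and line width."""

    splitting_90: float  # kHz, >= 0
    weight: float  # deuteron count x mole fraction, > 0
    linewidth: float = 100.0  # Lorentzian FWHM, Hz
    label: str = ""

    def __post_init__(self) -> None:
        if self.splitting_90 < 0:
            raise ValueError("splitting_90 must be >= 0 kHz")
        if self.splitting_90 > RIGID_SPLITTING_KHZ + 1e-9:
            raise ValueError(
                f"splitting_90 = {self.splitting_90} kHz exceeds the rigid limit "
                f"(3/4)·A_Q = {RIGID_SPLITTING_KHZ} kHz"
            )
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.linewidth < 0:
            raise ValueError("linewidth must be >= 0 Hz")


@dataclass(frozen=True)
class CSAComponent:
    """One phosphate environment: axially symmetric Δσ, δ_iso, width, weight."""

    delta_sigma: float  # ppm, signed
    delta_iso: float = 0.0  # ppm
    linewidth: float = 100.0  # Hz
    weight: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if abs(self.delta_sigma) >= 300.0:
            raise ValueError("|delta_sigma| must be < 300 ppm")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.linewidth < 0:
            raise ValueError("linewidth must be >= 0 Hz")


@dataclass(frozen=True)
class OrientationDistribution:
    """Distribution of bilayer-normal angles θ ∈ [0°, 90°].

    ``epsilon`` is the prolate field-deformation parameter: 0 recovers the
    random (sin θ) sphere; larger values deplete orientations near θ = 0.
    """

    epsilon: float = 0.0
    n_angles: int = 2048

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.n_angles < 64:
            raise ValueError("n_angles must be >= 64")

    def thetas_rad(self) -> np.ndarray:
        """Midpoints of equal-θ bins on [0, π/2]."""
        edges = np.linspace(0.0, np.pi / 2.0, self.n_angles + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def weights(self) -> np.ndarray:
        th = self.thetas_rad()
        cos2 = np.cos(th) ** 2
        w = np.sin(th) * np.maximum(0.0, 1.0 + self.epsilon * (1.0 - 3.0 * cos2) / 2.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("orientation weights sum to zero")
        return w / total


def orientation_weights(dist: OrientationDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Return (θ in degrees, normalised weights) on the midpoint grid."""
    return np.degrees(dist.thetas_rad()), dist.weights()


def _p2(cos_theta: np.ndarray | float):
    return (3.0 * np.asarray(cos_theta) ** 2 - 1.0) / 2.0


def effective_delta_sigma(delta_sigma_static: float, tilt: float) -> float:
    """Motionally averaged Δσ for a tensor axis tilted by ``tilt`` degrees.

    Fast axial rotation about the averaging axis scales the static
    anisotropy by the second Legendre polynomial, Δσ·(3cos²β − 1)/2; at
    the magic angle (54.7356°) the anisotropy vanishes.
    """
    if not 0.0 <= tilt <= 90.0:
        raise ValueError("tilt must be within [0, 90] degrees")
    return float(delta_sigma_static * _p2(np.cos(np.radians(tilt))))


# -- grids and accumulation -----------------------------------------------


def uniform_axis(lo: float, hi: float, n: int) -> np.ndarray:
    if n < 16 or hi <= lo:
        raise ValueError("need n >= 16 points and hi > lo")
    return np.linspace(lo, hi, n)


def quad_axis(max_splitting: float, n: int = 2048, margin: float = 1.25) -> np.ndarray:
    """Symmetric kHz grid wide enough for a ²H pattern of given splitting."""
    span = max(margin * max_splitting, 1.0)
    return uniform_axis(-span, span, n)


def csa_axis(
    components, n: int = 2048, margin: float = 0.25
) -> np.ndarray:
    """ppm grid covering all CSA pattern edges with relative margin."""
    lo, hi = [], []
    for c in components:
        e1 = c.delta_iso - c.delta_sigma / 3.0
        e2 = c.delta_iso + 2.0 * c.delta_sigma / 3.0
        pad = margin * max(abs(c.delta_sigma), 4.0)
        lo.append(min(e1, e2) - pad)
        hi.append(max(e1, e2) + pad)
    return uniform_axis(min(lo), max(hi), n)


def _deposit(freqs: np.ndarray, weights: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Accumulate weighted delta lines onto a uniform grid.

    Each line's weight is split linearly between the two bracketing grid
    points, so total deposited weight is conserved exactly.  Intensities
    are per unit axis (divided by the grid step).
    """
    n = axis.size
    dx = axis[1] - axis[0]
    pos = (freqs - axis[0]) / dx
    if np.any(pos < -1e-9) or np.any(pos > n - 1 + 1e-9):
        raise ValueError("axis grid too narrow for the requested pattern")
    pos = np.clip(pos, 0.0, n - 1.0)
    i0 = np.floor(pos).astype(np.intp)
    i0 = np.minimum(i0, n - 2)
    frac = pos - i0
    out = np.zeros(n)
    np.add.at(out, i0, weights * (1.0 - frac))
    np.add.at(out, i0 + 1, weights * frac)
    return out / dx


def _lorentz_kernel(n: int, dx: float, fwhm_axis: float) -> np.ndarray:
    gamma = fwhm_axis / 2.0
    d = (np.arange(n) - n // 2) * dx
    k = gamma / (np.pi * (d * d + gamma * gamma))
    return k / k.sum()


def apply_lorentzian_broadening(spectrum: Spectrum, lb: float) -> Spectrum:
    """Convolve with a unit-area Lorentzian of FWHM ``lb`` (Hz).

    Uses circular FFT convolution on the uniform grid, which conserves
    the total integral exactly; far Lorentzian tails wrap around the grid
    ends, so keep a margin of ≳10× the line width around the pattern.
    """
    if lb < 0:
        raise ValueError("line broadening must be >= 0 Hz")
    dx = spectrum.dx  # raises on non-uniform grid
    if lb == 0:
        return spectrum
    if spectrum.axis_kind == AXIS_KHZ:
        fwhm = lb / 1000.0
    else:  # ppm: 1 ppm = spectrometer_frequency Hz
        fwhm = lb / spectrum.spectrometer_frequency
    n = spectrum.n_points
    kernel = np.fft.ifftshift(_lorentz_kernel(n, dx, fwhm))
    out = np.real(np.fft.ifft(np.fft.fft(spectrum.intensity) * np.fft.fft(kernel)))
    return spectrum.with_intensity(out)


# -- single-component sub-spectra -----------------------------------------


def quad_powder_subspectrum(
    comp: QuadComponent,
    dist: OrientationDistribution,
    axis_grid: np.ndarray,
    spectrometer_frequency: float = DEFAULT_FREQ_2H_MHZ,
    broaden: bool = True,
) -> Spectrum:
    """Powder lineshape of one deuteron group on the given kHz grid.

    The spectrum is symmetric about 0; before broadening, the two most
    intense (90°) edges are separated by ``splitting_90`` and the outer
    shoulders by twice that.  The integral equals the component weight.
    """
    axis = np.asarray(axis_grid, dtype=float)
    s = comp.splitting_90
    if s > 0 and not (axis[0] <= -1.2 * s and axis[-1] >= 1.2 * s):
        raise ValueError(
            f"axis grid [{axis[0]:g}, {axis[-1]:g}] kHz too narrow: needs "
            f"±{1.2 * s:g} kHz for splitting_90 = {s:g} kHz"
        )
    w = dist.weights() * (comp.weight / 2.0)
    nu = s * _p2(np.cos(dist.thetas_rad()))
    intensity = _deposit(np.concatenate([nu, -nu]), np.concatenate([w, w]), axis)
    spec = Spectrum(
        axis=axis,
        intensity=intensity,
        nucleus="2H",
        spectrometer_frequency=spectrometer_frequency,
        axis_kind=AXIS_KHZ,
        label=comp.label,
    )
    if broaden and comp.linewidth > 0:
        spec = apply_lorentzian_broadening(spec, comp.linewidth)
    return spec


def csa_powder_subspectrum(
    comp: CSAComponent,
    dist: OrientationDistribution,
    axis_grid: np.ndarray,
    spectrometer_frequency: float = DEFAULT_FREQ_31P_MHZ,
    broaden: bool = True,
) -> Spectrum:
    """Powder lineshape of one phosphate environment on the given ppm grid."""
    axis = np.asarray(axis_grid, dtype=float)
    e_perp = comp.delta_iso - comp.delta_sigma / 3.0
    e_par = comp.delta_iso + 2.0 * comp.delta_sigma / 3.0
    lo, hi = min(e_perp, e_par), max(e_perp, e_par)
    pad = 0.02 * max(abs(comp.delta_sigma), 1.0)
    if not (axis[0] <= lo - pad and axis[-1] >= hi + pad):
        raise ValueError(
            f"axis grid [{axis[0]:g}, {axis[-1]:g}] ppm too narrow for pattern "
            f"edges [{lo:g}, {hi:g}] ppm"
        )
    nu = comp.delta_iso + (2.0 * comp.delta_sigma / 3.0) * _p2(
        np.cos(dist.thetas_rad())
    )
    intensity = _deposit(nu, dist.weights() * comp.weight, axis)
    spec = Spectrum(
        axis=axis,
        intensity=intensity,
        nucleus="31P",
        spectrometer_frequency=spectrometer_frequency,
        axis_kind=AXIS_PPM,
        label=comp.label,
    )
    if broaden and comp.linewidth > 0:
        spec = apply_lorentzian_broadening(spec, comp.linewidth)
    return spec


# -- composition expansion ------------------------------------------------


def composition_to_phosphorus_components(
    comp: MembraneComposition,
    params: pd.DataFrame | dict,
) -> list[CSAComponent]:
    """Expand a lipid composition into one CSA component per phosphate.

    ``params`` maps environment label → (Δσ ppm, δ_iso ppm, line width Hz),
    either as a DataFrame with columns ``label, delta_sigma_ppm,
    delta_iso_ppm, linewidth_hz`` or as a dict of 3-tuples.  Weights are
    stoichiometric (mol% per phosphate, normalised to sum 1); cholesterol
    contributes nothing.
    """
    if isinstance(params, pd.DataFrame):
        table = {
            str(r["label"]): (
                float(r["delta_sigma_ppm"]),
                float(r["delta_iso_ppm"]),
                float(r["linewidth_hz"]),
            )
            for _, r in params.iterrows()
        }
    else:
        table = {k: tuple(map(float, v)) for k, v in params.items()}
    out = []
    for label, weight in comp.phosphate_weights().items():
        if label not in table:
            raise KeyError(f"no 31P parameters supplied for phosphate {label!r}")
        dsig, diso, lw = table[label]
        out.append(
            CSAComponent(
                delta_sigma=dsig, delta_iso=diso, linewidth=lw, weight=weight, label=label
            )
        )
    return out


_CHAINS: dict[str, dict[int, int]] = {
    # perdeuterated palmitoyl sn-1 chain: CD2 at k=2..15, CD3 at k=16
    "palmitoyl-d31": {**{k: 2 for k in range(2, 16)}, 16: 3},
}
_CHAIN_ALIASES = {"POPC-d31": "palmitoyl-d31", "d31": "palmitoyl-d31"}
_SINGLE_RE = re.compile(r"^C(\d+)-d(\d+)$")


def _chain_inventory(chain) -> dict[int, int]:
    if isinstance(chain, dict):
        return {int(k): int(v) for k, v in chain.items()}
    name = _CHAIN_ALIASES.get(chain, chain)
    if name in _CHAINS:
        return dict(_CHAINS[name])
    m = _SINGLE_RE.match(str(chain))
    if m:  # single labelled position, e.g. C16-d3
        return {int(m.group(1)): int(m.group(2))}
    raise KeyError(f"unknown chain label {chain!r}")


def chain_to_quad_components(
    chain,
    profile: dict,
    linewidth_hz: float = 100.0,
    mole_fraction: float = 1.0,
) -> list[QuadComponent]:
    """Expand a deuterated chain into quadrupolar components.

    ``profile`` maps positions to 90°-edge splittings in kHz.  Keys may be
    single positions (int), inclusive ranges ``(lo, hi)`` sharing one
    splitting (the usual plateau group), or the string ``"plateau"``
    (= positions 2–10).  Every labelled position must be covered exactly
    once; merged groups become one component whose weight is the summed
    deuteron count.
    """
    inventory = _chain_inventory(chain)
    covered: set[int] = set()
    comps: list[QuadComponent] = []
    for key, value in profile.items():
        if key == "plateau":
            lo, hi = 2, 10
        elif isinstance(key, tuple):
            lo, hi = int(key[0]), int(key[1])
        else:
            lo = hi = int(key)
        members = [k for k in range(lo, hi + 1) if k in inventory]
        if not members:
            raise KeyError(f"profile entry {key!r} matches no labelled position")
        overlap = covered.intersection(members)
        if overlap:
            raise ValueError(f"positions {sorted(overlap)} assigned twice")
        covered.update(members)
        if isinstance(value, dict):
            splitting = float(value["splitting_khz"])
            lw = float(value.get("linewidth_hz", linewidth_hz))
        else:
            splitting = float(value)
            lw = linewidth_hz
        weight = mole_fraction * sum(inventory[k] for k in members)
        label = f"k{lo}" if lo == hi else f"k{lo}-{hi}"
        comps.append(
            QuadComponent(splitting_90=splitting, weight=weight, linewidth=lw, label=label)
        )
    missing = sorted(set(inventory) - covered)
    if missing:
        raise ValueError(f"no splitting supplied for positions {missing}")
    return comps


def compose(
    components,
    dist: OrientationDistribution,
    lb: float,
    axis_grid: np.ndarray,
    spectrometer_frequency: float | None = None,
    label: str = "",
) -> Spectrum:
    """Weighted superposition of component sub-spectra plus global broadening.

    Each component is simulated with its own intrinsic line width, summed,
    then the instrumental Lorentzian ``lb`` (Hz) is applied.  The integral
    equals the summed component weights.
    """
    components = list(components)
    if not components:
        raise ValueError("need at least one component")
    kinds = {type(c) for c in components}
    if len(kinds) > 1:
        raise ValueError("cannot mix 2H and 31P components in one spectrum")
    axis = np.asarray(axis_grid, dtype=float)
    total = None
    if isinstance(components[0], QuadComponent):
        freq = spectrometer_frequency or DEFAULT_FREQ_2H_MHZ
        for c in components:
            sub = quad_powder_subspectrum(c, dist, axis, freq)
            total = sub.intensity if total is None else total + sub.intensity
        spec = Spectrum(
            axis=axis, intensity=total, nucleus="2H",
            spectrometer_frequency=freq, axis_kind=AXIS_KHZ, label=label,
        )
    else:
        freq = spectrometer_frequency or DEFAULT_FREQ_31P_MHZ
        for c in components:
            sub = csa_powder_subspectrum(c, dist, axis, freq)
            total = sub.intensity if total is None else total + sub.intensity
        spec = Spectrum(
            axis=axis, intensity=total, nucleus="31P",
            spectrometer_frequency=freq, axis_kind=AXIS_PPM, label=label,
        )
    if lb > 0:
        spec = apply_lorentzian_broadening(spec, lb)
    return spec
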