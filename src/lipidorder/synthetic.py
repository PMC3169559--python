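"""Synthetic spectra with the statistical structure of the vesicle study.

The generator contains no physics of its own: every trace is produced by
the forward powder simulator from a machine-readable ground truth, then
Gaussian noise is added.  It emulates, per composition and temperature:

* ²H wide-line spectra of POPC-²H₃₁ (15 inequivalent deuteron groups,
  plateau merged k = 2–10), with the scenario plateau 2|S_CD| anchored
  to the measured values at 10 °C (0.47 pure POPC, 0.81 POPC/Chol, 0.69
  POPC/Chol/PI, 0.73 NER-like) and linear temperature trends;
* gel/fluid coexistence near T_m ≈ −5 °C as a two-component
  superposition whose gel part is a broad envelope of 120 kHz 90°-edge
  plateau width;
* a sharp isotropic contaminant line (< 5% by default);
* multi-phosphate ³¹P superpositions (up to 7 components) built from the
  per-composition anisotropy table, with optional prolate deformation.

Mid-chain (k = 11–15) splittings are synthetic defaults — a smooth
decreasing profile relative to the plateau — not measured values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compositions as _comp
from .compositions import COMPOSITIONS, P31_PARAMS, composition, p31_param_table
from .order_params import order_to_splitting
from .powder import (
    CSAComponent,
    OrientationDistribution,
    QuadComponent,
    chain_to_quad_components,
    compose,
    csa_axis,
    quad_axis,
)
from .spectra_io import Spectrum, write_spectrum

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "generate_scenario",
    "phase_coexistence_spectrum",
    "PLATEAU_TWO_SCD_10C",
]

#: scenario plateau 2|S_CD| at 10 °C; starred values are measured anchors,
#: the rest are synthetic defaults respecting the observed ordering
#: (cholesterol raises order, PtdIns lowers it, MV1 ≈ POPC/PI,
#: NER between POPC/Chol/PI and POPC/Chol)
PLATEAU_TWO_SCD_10C: dict[str, float] = {
    "POPC": 0.47,  # *
    "POPC/PI": 0.42,
    "POPC/PIP": 0.46,
    "POPC/PIP2": 0.47,
    "POPC/PI/PIP": 0.44,
    "POPC/PI/PIP2": 0.46,
    "MV1": 0.42,
    "MV2": 0.60,
    "POPC/Chol": 0.81,  # *
    "POPC/Chol/PI": 0.69,  # *
    "POPC/Chol/PI/PIP": 0.67,
    "POPC/Chol/PI/PIP2": 0.71,
    "NER": 0.73,  # *
}

#: synthetic mid-chain/methyl splittings relative to the plateau
RELATIVE_PROFILE: dict[int, float] = {11: 0.92, 12: 0.82, 13: 0.70, 14: 0.56, 15: 0.42, 16: 0.12}

#: 2|S_CD| change per °C: fluid phases soften faster than
#: cholesterol-rich (liquid-ordered) ones, which are quasi-constant
_SLOPE_FLUID = -0.005
_SLOPE_CHOL = -0.0015

#: 90°-edge plateau width of the broad gel envelope, kHz
GEL_WIDTH_KHZ = 120.0

#: generic per-environment anisotropies for compositions without a fitted row
_GENERIC_P31 = {
    "PC": -40.0, "PE": -31.0, "PS": -51.0,
    "PI_g": -60.0, "PIP_g": -58.0, "PIP2_g": -60.0,
    "PIP_4": -14.0, "PIP2_4": -14.0, "PIP2_5": -6.0,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic experiment: composition, temperatures, imperfections."""

    name: str
    temperatures: tuple[float, ...] = (-5.0, 0.0, 10.0, 20.0)
    noise: float = 0.01  # Gaussian sigma relative to max intensity
    lb: float = 200.0  # 2H instrumental broadening, Hz
    lb_p31: float = 100.0
    epsilon: float = 0.0
    gel_fraction: dict = field(default_factory=dict)  # temperature -> fraction
    isotropic_fraction: float = 0.03
    seed: int = 0
    n_points: int = 2048
    include_2h: bool = True
    include_p31: bool = True

    def __post_init__(self) -> None:
        composition(self.name)  # raises on unknown composition
        if not 0.0 <= self.isotropic_fraction < 1.0:
            raise ValueError("isotropic_fraction must be in [0, 1)")
        for t, f in self.gel_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"gel fraction at {t} °C outside [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind the generated spectra."""

    name: str
    seed: int
    epsilon: float
    per_temperature: dict  # temp -> plateau/per-k splittings, 2|S_CD|, fractions
    p31_components: list  # per-phosphate parameter dicts

    def to_json(self) -> str:
        d = asdict(self)
        d["per_temperature"] = {str(k): v for k, v in d["per_temperature"].items()}
        return json.dumps(d, indent=1, sort_keys=True)

    def thermal_frame(self) -> pd.DataFrame:
        rows = [
            {"composition": self.name, "temperature_c": t, **{
                "plateau_splitting_khz": v["plateau_splitting_khz"],
                "plateau_two_s_cd": v["plateau_two_s_cd"],
            }}
            for t, v in sorted(self.per_temperature.items())
        ]
        return pd.DataFrame(rows)


def plateau_two_scd(name: str, temperature: float) -> float:
    """Scenario ground-truth plateau 2|S_CD| at a temperature."""
    base = PLATEAU_TWO_SCD_10C[composition(name).name]
    slope = _SLOPE_CHOL if "Chol" in COMPOSITIONS[composition(name).name] else _SLOPE_FLUID
    return float(np.clip(base + slope * (temperature - 10.0), 0.05, 0.98))


def _fluid_components(name: str, temperature: float, linewidth_hz: float = 100.0):
    two_s = plateau_two_scd(name, temperature)
    plateau = order_to_splitting(two_s)
    profile = {"plateau": plateau}
    for k, rel in RELATIVE_PROFILE.items():
        profile[k] = rel * plateau
    comps = chain_to_quad_components("palmitoyl-d31", profile, linewidth_hz=linewidth_hz)
    truth = {
        "plateau_splitting_khz": plateau,
        "plateau_two_s_cd": two_s,
        "per_k_splittings_khz": {("2-10" if k == "plateau" else str(k)): float(v)
                                 for k, v in profile.items()},
    }
    return comps, truth


def phase_coexistence_spectrum(
    fluid,
    gel_width: float,
    gel_fraction: float,
    dist: OrientationDistribution,
    lb: float,
    axis_grid: np.ndarray,
    gel_linewidth_factor: float = 4.0,
) -> Spectrum:
    """Convex combination of a fluid chain spectrum and a broad gel one.

    The gel part reuses the fluid chain profile rescaled so its plateau
    sits at ``gel_width`` (120 kHz by default): a broad envelope with
    outer shoulders at the gel width plus a wide central methyl doublet,
    approximating the solid-ordered lineshape.  At gel_fraction 0.5 the
    central doublets of the two phases carry equal integrated intensity.
    """
    if not 0.0 <= gel_fraction <= 1.0:
        raise ValueError("gel_fraction must be in [0, 1]")
    fluid = list(fluid)
    scale = gel_width / max(c.splitting_90 for c in fluid)
    parts: list[QuadComponent] = []
    if gel_fraction < 1.0:
        parts += [
            QuadComponent(c.splitting_90, c.weight * (1.0 - gel_fraction),
                          c.linewidth, c.label)
            for c in fluid
        ]
    if gel_fraction > 0.0:
        parts += [
            QuadComponent(c.splitting_90 * scale, c.weight * gel_fraction,
                          c.linewidth * gel_linewidth_factor, f"gel:{c.label}")
            for c in fluid
        ]
    return compose(parts, dist, lb, axis_grid)


def _p31_components(name: str, lb_hint: float = 100.0) -> list[CSAComponent]:
    comp = composition(name)
    if comp.name in P31_PARAMS:
        params = p31_param_table(comp.name)
    else:
        params = pd.DataFrame(
            [
                {"label": lab, "delta_sigma_ppm": _GENERIC_P31[lab],
                 "delta_iso_ppm": _comp.DELTA_ISO_PPM[lab], "linewidth_hz": lb_hint}
                for lab in comp.phosphate_weights()
            ]
        )
    from .powder import composition_to_phosphorus_components

    return composition_to_phosphorus_components(comp, params)


def generate_scenario(
    spec: ScenarioSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, Spectrum], GroundTruth]:
    """Generate the scenario's spectra and their ground truth.

    Returns a mapping like ``{"2H_T10": Spectrum, "31P_T10": …}``.
    Deterministic for a given spec and seed; when ``out_dir`` is given
    the spectra, sidecars, ``ground_truth.json`` and a truth CSV are
    written there (byte-identical across runs).
    """
    name = composition(spec.name).name
    rng = np.random.default_rng(spec.seed)
    dist = OrientationDistribution(epsilon=spec.epsilon)
    any_gel = any(f > 0 for f in spec.gel_fraction.values())
    max_split = GEL_WIDTH_KHZ if any_gel else order_to_splitting(
        max(plateau_two_scd(name, t) for t in spec.temperatures)
    )
    axis_2h = quad_axis(max_split, n=spec.n_points)

    spectra: dict[str, Spectrum] = {}
    per_temp: dict[float, dict] = {}

    p31_comps = _p31_components(name) if spec.include_p31 else []
    if p31_comps:
        axis_31p = csa_axis(p31_comps, n=spec.n_points, margin=0.35)

    for t in spec.temperatures:
        gel = float(spec.gel_fraction.get(t, 0.0))
        truth_t = {"gel_fraction": gel, "isotropic_fraction": spec.isotropic_fraction}
        if spec.include_2h:
            comps, truth_fluid = _fluid_components(name, t)
            truth_t.update(truth_fluid)
            if spec.isotropic_fraction > 0:
                total_w = sum(c.weight for c in comps)
                iso_w = spec.isotropic_fraction / (1 - spec.isotropic_fraction) * total_w
                comps = comps + [
                    QuadComponent(0.0, iso_w, linewidth=50.0, label="iso")
                ]
            if gel > 0:
                spec2h = phase_coexistence_spectrum(
                    comps, GEL_WIDTH_KHZ, gel, dist, spec.lb, axis_2h
                )
            else:
                spec2h = compose(comps, dist, spec.lb, axis_2h)
            if spec.noise > 0:
                sigma = spec.noise * np.abs(spec2h.intensity).max()
                spec2h = spec2h.with_intensity(
                    spec2h.intensity + rng.normal(0.0, sigma, spec2h.n_points)
                )
            spec2h = spec2h.with_intensity(
                spec2h.intensity,
                temperature=t,
                label=f"{name} 2H {t:g}C",
                meta={"seed": spec.seed, "scenario": name},
            )
            spectra[f"2H_T{t:g}"] = spec2h
        if spec.include_p31:
            spec31 = compose(p31_comps, dist, spec.lb_p31, axis_31p)
            if spec.noise > 0:
                sigma = spec.noise * np.abs(spec31.intensity).max()
                spec31 = spec31.with_intensity(
                    spec31.intensity + rng.normal(0.0, sigma, spec31.n_points)
                )
            spec31 = spec31.with_intensity(
                spec31.intensity,
                temperature=t,
                label=f"{name} 31P {t:g}C",
                meta={"seed": spec.seed, "scenario": name},
            )
            spectra[f"31P_T{t:g}"] = spec31
        per_temp[t] = truth_t

    truth = GroundTruth(
        name=name,
        seed=spec.seed,
        epsilon=spec.epsilon,
        per_temperature=per_temp,
        p31_components=[
            {"label": c.label, "delta_sigma_ppm": c.delta_sigma,
             "delta_iso_ppm": c.delta_iso, "linewidth_hz": c.linewidth,
             "weight": c.weight}
            for c in p31_comps
        ],
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in sorted(spectra):
            write_spectrum(spectra[key], out / f"{key}.txt")
        (out / "ground_truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
        if spec.include_2h:
            truth.thermal_frame().to_csv(out / "truth_thermal.csv", index=False)
    return spectra, truth
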