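"""Membrane compositions and per-lipid NMR inventories.

A :class:`MembraneComposition` lists lipids with their molar proportions
and knows, for each lipid, how many distinct phosphate environments it
contributes to a ³¹P spectrum and whether it carries a perdeuterated
chain visible in ²H spectra.

Phosphate environment labels
----------------------------
``PC, PE, PS`` — the phosphodiester of the corresponding glycerophospholipid;
``PI_g, PIP_g, PIP2_g`` — the glycerol-bound phosphodiester of PtdIns,
PtdInsP and PtdInsP₂; ``PIP_4, PIP2_4, PIP2_5`` — the monoester phosphates
on the inositol ring (4-position of PtdInsP, 4- and 5-positions of
PtdInsP₂).  Cholesterol carries no phosphate.

The module ships the model-membrane compositions used throughout
(``POPC``, ``POPC/PI`` … ``MV1``, ``MV2``, ``NER``) and a default table of
axially symmetric shielding anisotropies Δσ, isotropic shifts δ_iso and
line widths per phosphate environment for each of those systems, as
recovered by multi-component lineshape fitting of the corresponding
vesicle spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "A_Q_KHZ",
    "LipidEntry",
    "MembraneComposition",
    "LIPID_INVENTORY",
    "COMPOSITIONS",
    "P31_PARAMS",
    "DELTA_ISO_PPM",
    "composition",
    "p31_param_table",
]

#: static quadrupolar coupling constant of the C–D bond, kHz
A_Q_KHZ = 167.0

#: rigid-limit 90°-edge quadrupolar splitting, kHz
RIGID_SPLITTING_KHZ = 0.75 * A_Q_KHZ

#: distinct phosphate environments per lipid
LIPID_INVENTORY: dict[str, tuple[str, ...]] = {
    "POPC": ("PC",),
    "POPE": ("PE",),
    "POPS": ("PS",),
    "PI": ("PI_g",),
    "PIP": ("PIP_g", "PIP_4"),
    "PIP2": ("PIP2_g", "PIP2_4", "PIP2_5"),
    "Chol": (),
}

#: lipids that can carry the perdeuterated palmitoyl (d31) chain
_DEUTERATED = {"POPC": "palmitoyl-d31"}


@dataclass(frozen=True)
class LipidEntry:
    name: str
    mol_percent: float
    phosphate_labels: tuple[str, ...]
    deuterated_chain: str | None = None

    @property
    def n_phosphates(self) -> int:
        return len(self.phosphate_labels)

    def __post_init__(self) -> None:
        if self.mol_percent <= 0:
            raise ValueError(f"{self.name}: mol_percent must be > 0")
        if not 0 <= self.n_phosphates <= 3:
            raise ValueError(f"{self.name}: phosphate count must be 0..3")


@dataclass(frozen=True)
class MembraneComposition:
    """A lipid mixture given as molar proportions.

    Proportions are stored exactly as supplied (they may be ratios that do
    not total 100); :meth:`mole_fractions` normalises.  When a composition
    is declared a complete inventory (``require_total=True``) the total
    must be 100 within ±1 mol% (the accuracy of the preparation).
    """

    name: str
    lipids: tuple[LipidEntry, ...]
    require_total: bool = False
    a_q_khz: float = A_Q_KHZ

    def __post_init__(self) -> None:
        if not self.lipids:
            raise ValueError("composition needs at least one lipid")
        total = sum(l.mol_percent for l in self.lipids)
        if self.require_total and abs(total - 100.0) > 1.0:
            raise ValueError(
                f"{self.name}: mol% total {total:.2f} differs from 100 by more than 1"
            )

    @classmethod
    def from_mol_percent(
        cls, name: str, mol_percent: dict[str, float], require_total: bool = False
    ) -> "MembraneComposition":
        entries = []
        for lipid, pct in mol_percent.items():
            if lipid not in LIPID_INVENTORY:
                raise KeyError(
                    f"unknown lipid {lipid!r}; known: {sorted(LIPID_INVENTORY)}"
                )
            entries.append(
                LipidEntry(
                    name=lipid,
                    mol_percent=float(pct),
                    phosphate_labels=LIPID_INVENTORY[lipid],
                    deuterated_chain=_DEUTERATED.get(lipid),
                )
            )
        return cls(name=name, lipids=tuple(entries), require_total=require_total)

    def mole_fractions(self) -> dict[str, float]:
        total = sum(l.mol_percent for l in self.lipids)
        return {l.name: l.mol_percent / total for l in self.lipids}

    def phosphate_weights(self) -> dict[str, float]:
        """Relative ³¹P abundance per environment, normalised to sum 1.

        Each phosphate of a lipid contributes that lipid's molar
        proportion once; cholesterol contributes nothing.
        """
        raw: dict[str, float] = {}
        for lipid in self.lipids:
            for label in lipid.phosphate_labels:
                raw[label] = raw.get(label, 0.0) + lipid.mol_percent
        total = sum(raw.values())
        if total == 0:
            raise ValueError(f"{self.name}: no phosphates in composition")
        return {k: v / total for k, v in raw.items()}


#: model membrane systems (molar proportions as prepared)
COMPOSITIONS: dict[str, dict[str, float]] = {
    "POPC": {"POPC": 100},
    "POPC/PI": {"POPC": 30, "PI": 20},
    "POPC/PIP": {"POPC": 30, "PIP": 18},
    "POPC/PIP2": {"POPC": 30, "PIP2": 12},
    "POPC/PI/PIP": {"POPC": 30, "PI": 20, "PIP": 18},
    "POPC/PI/PIP2": {"POPC": 30, "PI": 20, "PIP2": 12},
    "MV1": {"POPC": 30, "PI": 20, "PIP": 18, "PIP2": 12},
    "MV2": {"POPC": 30, "Chol": 20, "POPE": 25, "POPS": 5, "PI": 20},
    "POPC/Chol": {"POPC": 58, "Chol": 42},
    "POPC/Chol/PI": {"POPC": 28, "Chol": 42, "PI": 30},
    "POPC/Chol/PI/PIP": {"POPC": 28, "Chol": 42, "PI": 23, "PIP": 7},
    "POPC/Chol/PI/PIP2": {"POPC": 28, "Chol": 42, "PI": 23, "PIP2": 7},
    "NER": {"POPC": 28, "Chol": 42, "PI": 16, "PIP": 7, "PIP2": 7},
}

_ALIASES = {"MV1-like": "MV1", "MV2-like": "MV2", "NER-like": "NER", "NERs": "NER"}


def composition(name: str) -> MembraneComposition:
    """Look up a shipped composition by name (aliases like 'NER-like' work)."""
    key = _ALIASES.get(name, name)
    if key not in COMPOSITIONS:
        raise KeyError(f"unknown composition {name!r}; known: {sorted(COMPOSITIONS)}")
    return MembraneComposition.from_mol_percent(key, COMPOSITIONS[key])


#: isotropic ³¹P chemical shifts per phosphate environment, ppm
#: (PE/PS values are synthetic defaults — not independently measured)
DELTA_ISO_PPM: dict[str, float] = {
    "PC": -1.0,
    "PE": 0.0,
    "PS": 0.0,
    "PI_g": -0.4,
    "PIP_g": -0.3,
    "PIP2_g": -0.4,
    "PIP_4": 1.5,
    "PIP2_4": 1.0,
    "PIP2_5": 0.2,
}

#: fitted Δσ (ppm) per phosphate environment, by composition
P31_PARAMS: dict[str, dict[str, float]] = {
    "POPC": {"PC": -47.0},
    "POPC/PI": {"PC": -40.0, "PI_g": -61.0},
    "POPC/PIP": {"PC": -34.5, "PIP_g": -58.0, "PIP_4": -14.0},
    "POPC/PIP2": {"PC": -34.8, "PIP2_g": -60.0, "PIP2_4": -14.0, "PIP2_5": -6.0},
    "MV1": {
        "PC": -32.0,
        "PI_g": -60.0,
        "PIP_g": -60.0,
        "PIP2_g": -60.0,
        "PIP_4": -14.0,
        "PIP2_4": -14.0,
        "PIP2_5": -3.0,
    },
    "POPC/Chol": {"PC": -40.8},
    "POPC/Chol/PI": {"PC": -37.8, "PI_g": -54.9},
    "NER": {
        "PC": -35.2,
        "PI_g": -56.0,
        "PIP_g": -56.0,
        "PIP2_g": -56.0,
        "PIP_4": -11.5,
        "PIP2_4": -11.5,
        "PIP2_5": -3.0,
    },
    "MV2": {"PC": -38.0, "PE": -31.0, "PS": -51.0, "PI_g": -55.0},
}

#: default intrinsic Lorentzian line width for ³¹P components, Hz
DEFAULT_P31_LINEWIDTH_HZ = 100.0


def p31_param_table(name: str, linewidth_hz: float = DEFAULT_P31_LINEWIDTH_HZ) -> pd.DataFrame:
    """Per-environment (Δσ, δ_iso, line width) table for a composition.

    Mirrors the CSV layout ``label, delta_sigma_ppm, delta_iso_ppm,
    linewidth_hz``.
    """
    key = _ALIASES.get(name, name)
    if key not in P31_PARAMS:
        raise KeyError(f"no 31P parameters for {name!r}; known: {sorted(P31_PARAMS)}")
    rows = [
        {
            "label": label,
            "delta_sigma_ppm": dsig,
            "delta_iso_ppm": DELTA_ISO_PPM[label],
            "linewidth_hz": linewidth_hz,
        }
        for label, dsig in P31_PARAMS[key].items()
    ]
    return pd.DataFrame(rows)
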