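"""Quadrupolar splittings → C–D bond order parameters and thermal profiles.

The 90°-edge splitting of a C–D doublet maps linearly to the bond order
parameter through the static quadrupolar coupling constant A_Q = 167 kHz:

    Δν_Q(90°) = (3/4)·A_Q·|S_CD|   ⇔   |S_CD| = (4/3)·Δν_Q(90°)/A_Q

Plateau positions (k = 2 to 8–10, near the glycerol backbone) have their
average C–D bond at 90° to the long molecular axis, so twice |S_CD| is
the headline quantity: 2|S_CD| runs from 0 (fully disordered fluid) to 1
(rigid, fully ordered).  The terminal methyl rotates fast about the
chain axis, scaling its splitting by |P₂(cos 109.47°)| = 1/3; the methyl
entry therefore carries both the raw mapping and a ×3 chain-axis
corrected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .compositions import A_Q_KHZ
from .spectra_io import Spectrum

__all__ = [
    "MeasuredSplittings",
    "OrderProfile",
    "measure_splittings",
    "splitting_to_order",
    "order_to_splitting",
    "assemble_order_profile",
    "thermal_table",
    "SPLITTING_ACCURACY_KHZ",
]

#: experimental accuracy of a splitting measurement, kHz
SPLITTING_ACCURACY_KHZ = 1.0

#: fast CD3 rotation scales the methyl splitting by |P2(cos 109.47°)| = 1/3
METHYL_CORRECTION = 3.0


@dataclass(frozen=True)
class MeasuredSplittings:
    """Splittings (kHz, descending) read off an oriented-like spectrum."""

    splittings: tuple[float, ...]
    n_expected: int | None = None
    isotropic_detected: bool = False

    @property
    def resolved(self) -> int:
        return len(self.splittings)

    def __iter__(self):
        return iter(self.splittings)


def measure_splittings(
    oriented: Spectrum,
    n_expected: int | None = None,
    prominence_frac: float = 0.04,
    pairing_tol_khz: float | None = None,
) -> MeasuredSplittings:
    """Detect symmetric peak pairs and return their splittings, descending.

    Peaks must exceed ``prominence_frac`` of the maximum intensity; a
    positive and a negative peak are paired when their |ν| differ by less
    than the pairing tolerance (0.5 kHz or 3 grid steps, whichever is
    larger).  A line at ν ≈ 0 is reported as an isotropic contaminant,
    not a splitting.  If fewer than ``n_expected`` pairs resolve, what
    was found is returned with its resolved count.
    """
    y = oriented.intensity
    if not np.any(y > 0):
        raise ValueError("no positive intensity in spectrum")
    tol = pairing_tol_khz if pairing_tol_khz is not None else max(0.5, 3.0 * oriented.dx)
    prom = prominence_frac * y.max()
    idx, _ = scipy.signal.find_peaks(y, prominence=prom)
    if idx.size == 0:
        raise ValueError("no peaks above the noise threshold")
    nu = oriented.axis[idx]

    iso = np.abs(nu) < tol
    pos = sorted(nu[(~iso) & (nu > 0)], reverse=True)
    neg = list(nu[(~iso) & (nu < 0)])
    splittings: list[float] = []
    for p in pos:
        match = None
        for m in neg:
            if abs(abs(m) - p) < tol:
                if match is None or abs(abs(m) - p) < abs(abs(match) - p):
                    match = m
        if match is not None:
            neg.remove(match)
            splittings.append(float(p - match))
    return MeasuredSplittings(
        splittings=tuple(sorted(splittings, reverse=True)),
        n_expected=n_expected,
        isotropic_detected=bool(iso.any()),
    )


def splitting_to_order(
    splitting: float, a_q: float = A_Q_KHZ, methyl: bool = False
) -> dict[str, float]:
    """Map a 90°-edge splitting (kHz) to {s_cd, two_s_cd}.

    With ``methyl=True`` the mapped value is multiplied by 3 to undo the
    fast CD₃ rotational averaging and report chain-axis order.
    """
    if splitting < 0:
        raise ValueError("splitting must be >= 0 kHz")
    bound = 0.75 * a_q / (METHYL_CORRECTION if methyl else 1.0)
    if splitting > bound + 1e-9:
        raise ValueError(
            f"splitting {splitting} kHz exceeds the rigid bound {bound} kHz"
        )
    s = (4.0 / 3.0) * splitting / a_q
    if methyl:
        s *= METHYL_CORRECTION
    return {"s_cd": s, "two_s_cd": 2.0 * s}


def order_to_splitting(
    two_s_cd: float, a_q: float = A_Q_KHZ, methyl: bool = False
) -> float:
    """Inverse of :func:`splitting_to_order` on the 2|S_CD| scale."""
    if not 0.0 <= two_s_cd <= 1.0 + 1e-9:
        raise ValueError("two_s_cd must lie in [0, 1]")
    s = (3.0 / 8.0) * a_q * two_s_cd
    if methyl:
        s /= METHYL_CORRECTION
    return s


def order_uncertainty(splitting_err_khz: float = SPLITTING_ACCURACY_KHZ, a_q: float = A_Q_KHZ) -> float:
    """±1 kHz on a splitting propagated linearly to the 2|S_CD| scale."""
    return 2.0 * (4.0 / 3.0) * splitting_err_khz / a_q


@dataclass(frozen=True)
class OrderProfile:
    """Per-position order parameters at one temperature.

    ``entries`` maps ``"plateau"`` (merged k = 2–10 group) and chain
    positions 11…16 to {splitting, s_cd, two_s_cd}; the methyl (k = 16)
    entry additionally carries the ×3 chain-axis corrected values.
    """

    temperature: float
    entries: dict = field(default_factory=dict)
    label: str = ""
    flags: tuple[str, ...] = ()

    @property
    def plateau(self) -> dict | None:
        return self.entries.get("plateau")

    @property
    def methyl(self) -> dict | None:
        return self.entries.get(16)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, e in self.entries.items():
            rows.append(
                {
                    "composition": self.label,
                    "temperature_c": self.temperature,
                    "position_k": "2-10" if key == "plateau" else str(key),
                    "splitting_khz": e["splitting"],
                    "splitting_err_khz": SPLITTING_ACCURACY_KHZ,
                    "s_cd": e["s_cd"],
                    "two_s_cd": e["two_s_cd"],
                    "flags": ";".join(self.flags),
                }
            )
        return pd.DataFrame(rows)


def assemble_order_profile(
    splittings,
    temperature: float,
    label: str = "",
    a_q: float = A_Q_KHZ,
) -> OrderProfile:
    """Assign measured splittings to chain positions.

    The largest (possibly merged) splitting is the plateau (k = 2–10),
    the smallest is the terminal methyl (k = 16), and intermediates fill
    k = 11…15 in descending order.  Degenerate inputs yield partial
    profiles flagged as such.
    """
    vals = sorted((float(s) for s in splittings), reverse=True)
    if not vals:
        raise ValueError("need at least one splitting")
    flags: list[str] = []
    entries: dict = {"plateau": {"splitting": vals[0], **splitting_to_order(vals[0], a_q)}}
    if len(vals) == 1:
        flags.append("plateau-only")
    else:
        mids = vals[1:-1]
        if len(mids) > 5:
            flags.append(f"unassigned:{len(mids) - 5}")
            mids = mids[:5]
        for k, s in zip(range(11, 16), mids):
            entries[k] = {"splitting": s, **splitting_to_order(s, a_q)}
        if len(mids) < 5:
            flags.append("partial")
        methyl_raw = vals[-1]
        corrected = splitting_to_order(methyl_raw, a_q, methyl=True)
        entries[16] = {
            "splitting": methyl_raw,
            **splitting_to_order(methyl_raw, a_q),
            "s_cd_chain": corrected["s_cd"],
            "two_s_cd_chain": corrected["two_s_cd"],
        }
    return OrderProfile(
        temperature=temperature, entries=entries, label=label, flags=tuple(flags)
    )


def thermal_table(profiles) -> pd.DataFrame:
    """Plateau 2|S_CD| versus temperature and composition.

    One row per (composition, temperature); the ±1 kHz splitting
    accuracy is propagated to the order-parameter column.  Duplicate
    (composition, temperature) pairs are rejected.
    """
    rows = []
    seen = set()
    for p in profiles:
        key = (p.label, p.temperature)
        if key in seen:
            raise ValueError(f"duplicate profile for composition/temperature {key}")
        seen.add(key)
        e = p.plateau
        if e is None:
            raise ValueError(f"profile {key} has no plateau entry")
        rows.append(
            {
                "composition": p.label,
                "temperature_c": p.temperature,
                "plateau_splitting_khz": e["splitting"],
                "splitting_err_khz": SPLITTING_ACCURACY_KHZ,
                "plateau_two_s_cd": e["two_s_cd"],
                "two_s_cd_err": order_uncertainty(),
            }
        )
    return pd.DataFrame(rows).sort_values(["composition", "temperature_c"]).reset_index(
        drop=True
    )
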