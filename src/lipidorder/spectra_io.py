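"""Spectrum container, axis conversions and text-file round tripping.

All downstream stages operate on one canonical in-memory representation:
a 1-D frequency-domain trace with a strictly increasing axis.  The
canonical axis unit is kHz offset from the carrier for deuterium wide-line
spectra and ppm (relative to 85% H3PO4 = 0 ppm) for phosphorus spectra.
Conversions between the two conventions are always explicit.

On disk a spectrum is a two-column UTF-8 text file (axis, intensity; '#'
comments) accompanied by a JSON sidecar ``<path>.json`` holding the
metadata (nucleus, spectrometer frequency, axis kind, temperature, label).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "AXIS_KHZ",
    "AXIS_PPM",
    "CANONICAL_AXIS",
    "convert_axis",
    "read_spectrum",
    "write_spectrum",
]

AXIS_KHZ = "kHz"
AXIS_PPM = "ppm"
_AXIS_KINDS = (AXIS_KHZ, AXIS_PPM)

#: canonical on-disk axis convention per nucleus
CANONICAL_AXIS = {"2H": AXIS_KHZ, "31P": AXIS_PPM}

_SIDECAR_REQUIRED = ("nucleus", "spectrometer_frequency_mhz", "axis_kind")

_MIN_POINTS = 16


@dataclass(frozen=True)
class Spectrum:
    """A 1-D frequency-domain NMR trace with acquisition metadata.

    Parameters
    ----------
    axis
        Strictly increasing frequency values; kHz offset from the carrier
        (²H) or ppm relative to 85% H₃PO₄ (³¹P).
    intensity
        Real intensities, same length as ``axis``.
    nucleus
        ``"2H"`` or ``"31P"``.
    spectrometer_frequency
        Larmor frequency of the observed nucleus in MHz.
    temperature
        Sample temperature in °C (optional).
    """

    axis: np.ndarray
    intensity: np.ndarray
    nucleus: str
    spectrometer_frequency: float
    axis_kind: str = AXIS_KHZ
    temperature: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if self.nucleus not in CANONICAL_AXIS:
            raise ValueError(f"unknown nucleus {self.nucleus!r}; expected 2H or 31P")
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(f"unknown axis kind {self.axis_kind!r}; expected kHz or ppm")
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if axis.size != intensity.size:
            raise ValueError(
                f"axis ({axis.size}) and intensity ({intensity.size}) lengths differ"
            )
        if axis.size < _MIN_POINTS:
            raise ValueError(f"spectrum needs >= {_MIN_POINTS} points, got {axis.size}")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(intensity))):
            raise ValueError("axis and intensity must be finite")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if not self.spectrometer_frequency > 0:
            raise ValueError("spectrometer_frequency must be > 0 MHz")

    # -- convenience ------------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    @property
    def dx(self) -> float:
        """Grid step; raises on non-uniform grids."""
        steps = np.diff(self.axis)
        step = float(steps[0])
        if not np.allclose(steps, step, rtol=1e-8, atol=1e-12):
            raise ValueError("axis grid is not uniform")
        return step

    def is_uniform(self) -> bool:
        steps = np.diff(self.axis)
        return bool(np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12))

    def integral(self) -> float:
        """Total area under the trace (rectangle rule, uniform grid)."""
        return float(self.intensity.sum() * self.dx)

    def first_moment(self) -> float:
        """Intensity-weighted mean frequency (diagnostic utility)."""
        total = self.intensity.sum()
        if total == 0:
            raise ValueError("all-zero spectrum has no first moment")
        return float((self.axis * self.intensity).sum() / total)

    def with_intensity(self, intensity: np.ndarray, **kwargs) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float), **kwargs)

    def is_canonical(self) -> bool:
        return CANONICAL_AXIS[self.nucleus] == self.axis_kind


def convert_axis(spectrum: Spectrum, target: str) -> Spectrum:
    """Convert the axis between kHz offset and ppm.

    The scaling is shift[ppm] × spectrometer frequency[MHz] / 1000 =
    offset[kHz]; intensities are untouched, so the round trip is the
    identity.
    """
    if target not in _AXIS_KINDS:
        raise ValueError(f"unknown axis kind {target!r}; expected one of {_AXIS_KINDS}")
    if target == spectrum.axis_kind:
        return spectrum
    f = spectrum.spectrometer_frequency
    if target == AXIS_KHZ:  # ppm -> kHz
        axis = spectrum.axis * f / 1000.0
    else:  # kHz -> ppm
        axis = spectrum.axis * 1000.0 / f
    return replace(spectrum, axis=axis, axis_kind=target)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write the two-column text file plus its JSON metadata sidecar.

    Values are stored with 17 significant digits so the read/write round
    trip is bit-faithful for doubles.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "# lipidorder spectrum",
        f"# columns: axis[{spectrum.axis_kind}] intensity",
    ]
    for x, y in zip(spectrum.axis, spectrum.intensity):
        lines.append(f"{x:.17g} {y:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta = {
        "nucleus": spectrum.nucleus,
        "spectrometer_frequency_mhz": spectrum.spectrometer_frequency,
        "axis_kind": spectrum.axis_kind,
        "temperature_c": spectrum.temperature,
        "label": spectrum.label,
    }
    meta.update(spectrum.meta)
    _sidecar_path(path).write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum`.

    Raises with the offending line number on non-numeric rows and with the
    missing key names when the sidecar is incomplete.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta or meta[k] is None]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing required keys: {', '.join(missing)}")

    axis_vals: list[float] = []
    int_vals: list[float] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {body!r}") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"{path}:{lineno}: non-finite value")
        axis_vals.append(x)
        int_vals.append(y)

    nucleus = str(meta["nucleus"])
    axis_kind = str(meta["axis_kind"])
    if CANONICAL_AXIS.get(nucleus) != axis_kind:
        raise ValueError(
            f"{sidecar}: axis kind {axis_kind!r} is not canonical for nucleus "
            f"{nucleus!r} (expected {CANONICAL_AXIS.get(nucleus)!r})"
        )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("nucleus", "spectrometer_frequency_mhz", "axis_kind", "temperature_c", "label")
    }
    return Spectrum(
        axis=np.asarray(axis_vals),
        intensity=np.asarray(int_vals),
        nucleus=nucleus,
        spectrometer_frequency=float(meta["spectrometer_frequency_mhz"]),
        axis_kind=axis_kind,
        temperature=meta.get("temperature_c"),
        label=str(meta.get("label") or ""),
        meta=extra,
    )
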