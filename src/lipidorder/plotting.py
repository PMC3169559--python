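"""Static figures for spectra and thermal order-parameter curves.

Presentation-layer only: ppm axes are drawn decreasing left-to-right,
as is conventional for chemical shifts, while all numeric code keeps
axes stored increasing.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .spectra_io import AXIS_PPM, Spectrum

__all__ = ["plot_spectrum", "plot_thermal"]


def plot_spectrum(spectrum: Spectrum, ax=None, **kwargs):
    """Plot one trace; ppm axes are inverted for display."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spectrum.axis, spectrum.intensity, **kwargs)
    ax.set_xlabel(
        "chemical shift (ppm)" if spectrum.axis_kind == AXIS_PPM else "frequency (kHz)"
    )
    ax.set_ylabel("intensity (a.u.)")
    if spectrum.axis_kind == AXIS_PPM and not ax.xaxis_inverted():
        ax.invert_xaxis()
    if spectrum.label:
        ax.set_title(spectrum.label)
    return ax


def plot_thermal(table: pd.DataFrame, ax=None):
    """Plateau 2|S_CD| versus temperature, one curve per composition."""
    if ax is None:
        _, ax = plt.subplots()
    for name, grp in table.groupby("composition"):
        grp = grp.sort_values("temperature_c")
        ax.errorbar(
            grp["temperature_c"],
            grp["plateau_two_s_cd"],
            yerr=grp.get("two_s_cd_err"),
            marker="o",
            label=name,
        )
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("plateau 2|S$_{CD}$|")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax
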