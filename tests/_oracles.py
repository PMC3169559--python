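"""Independent brute-force oracles used to validate the lineshape code.

These deliberately avoid the package's accumulation path: patterns are
built by histogramming the per-orientation frequencies of a dense
orientation ensemble (>= 1e6 orientations drawn on a uniform theta grid,
weighted by the orientation distribution).
"""

from __future__ import annotations

import numpy as np


def _theta_ensemble(epsilon: float, n_samples: int):
    edges = np.linspace(0.0, np.pi / 2.0, n_samples + 1)
    th = 0.5 * (edges[:-1] + edges[1:])
    w = np.sin(th) * np.maximum(0.0, 1.0 + epsilon * (1.0 - 3.0 * np.cos(th) ** 2) / 2.0)
    return th, w / w.sum()


def brute_force_quad_hist(
    splitting_90: float, epsilon: float, bin_edges: np.ndarray, n_samples: int = 1_000_000
) -> np.ndarray:
    """Normalised histogram of a quadrupolar doublet powder pattern."""
    th, w = _theta_ensemble(epsilon, n_samples)
    p2 = (3.0 * np.cos(th) ** 2 - 1.0) / 2.0
    nu = splitting_90 * p2
    h, _ = np.histogram(
        np.concatenate([nu, -nu]), bins=bin_edges,
        weights=np.concatenate([w, w]) / 2.0,
    )
    return h


def brute_force_csa_hist(
    delta_sigma: float, delta_iso: float, epsilon: float,
    bin_edges: np.ndarray, n_samples: int = 1_000_000,
) -> np.ndarray:
    """Normalised histogram of an axially symmetric CSA powder pattern."""
    th, w = _theta_ensemble(epsilon, n_samples)
    p2 = (3.0 * np.cos(th) ** 2 - 1.0) / 2.0
    nu = delta_iso + (2.0 * delta_sigma / 3.0) * p2
    h, _ = np.histogram(nu, bins=bin_edges, weights=w)
    return h


def rebin_spectrum(axis: np.ndarray, intensity: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin masses of a gridded spectrum on a coarser comparison grid."""
    dx = axis[1] - axis[0]
    h, _ = np.histogram(axis, bins=bin_edges, weights=intensity * dx)
    return h
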