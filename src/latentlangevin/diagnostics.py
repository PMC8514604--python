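"""Shape diagnostics for comparing inferred and reference potentials."""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

__all__ = ["central_mask", "potential_rmse", "count_interior_extrema",
           "smoothed"]


def central_mask(nodes: np.ndarray, fraction: float = 0.8) -> np.ndarray:
    """Boolean mask selecting the central ``fraction`` of the domain."""
    return np.abs(nodes) <= fraction


def potential_rmse(phi: np.ndarray, phi_ref: np.ndarray, nodes: np.ndarray,
                   fraction: float = 0.8) -> float:
    """RMSE between two gauge-fixed potentials over the central domain."""
    m = central_mask(nodes, fraction)
    return float(np.sqrt(np.mean((phi[m] - phi_ref[m]) ** 2)))


def count_interior_extrema(phi: np.ndarray, nodes: np.ndarray,
                           prominence: float = 0.5,
                           fraction: float = 0.8) -> int:
    """Number of interior maxima + minima of the potential.

    Counted over the central part of the domain with a prominence
    threshold, so that small residual optimization wiggles (typically
    well below 0.5 in potential units) are not mistaken for features
    such as the barriers of a stepping potential (height ~1.5).
    """
    m = central_mask(nodes, fraction)
    v = phi[m]
    n_max = len(find_peaks(v, prominence=prominence)[0])
    n_min = len(find_peaks(-v, prominence=prominence)[0])
    return n_max + n_min


def smoothed(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average used for trend checks on noisy traces."""
    v = np.asarray(values, dtype=float)
    if len(v) < window:
        return v.copy()
    return np.convolve(v, np.ones(window) / window, mode="valid")
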