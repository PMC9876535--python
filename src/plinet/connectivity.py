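"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute time-average of the sign of the
sine of their instantaneous phase difference,

    PLI = | < sign( sin(φ_i − φ_j) ) > |  ∈ [0, 1].

It measures the asymmetry of the phase-difference distribution: 1 for a
perfectly consistent nonzero lag, 0 when positive and negative lags balance.
Zero-lag and antiphase relations (Δφ ≡ 0 or π) give PLI = 0, which is what
makes the index insensitive to volume conduction and to the choice of
reference electrode.  Samples with Δφ exactly 0 or π contribute nothing
(``sign(0) = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import BandDefinition, PhaseEpoch

__all__ = ["ConnectivityMatrix", "pli_pair", "pli_epoch"]

# sin(Δφ) below this magnitude counts as an exact zero/antiphase sample, so
# the volume-conduction blindness (PLI = 0 at Δφ ≡ 0 or π) is exact despite
# floating-point representation of π.
_SIN_TOL = 1e-9


def _signed_lags(delta_phi: np.ndarray) -> np.ndarray:
    s = np.sin(delta_phi)
    return np.sign(np.where(np.abs(s) < _SIN_TOL, 0.0, s))


@dataclass
class ConnectivityMatrix:
    """Symmetric per-epoch PLI matrix with zero diagonal, entries in [0, 1]."""

    weights: np.ndarray  # (n_channels, n_channels)
    band: BandDefinition
    epoch_index: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.weights = w


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI between two instantaneous-phase series of equal length (≥ 2)."""
    pi = np.asarray(phase_i, dtype=float)
    pj = np.asarray(phase_j, dtype=float)
    if pi.shape != pj.shape:
        raise ValueError(f"phase series shapes differ: {pi.shape} vs {pj.shape}")
    if pi.ndim != 1 or pi.size < 2:
        raise ValueError("phase series must be one-dimensional with length >= 2")
    return float(np.abs(np.mean(_signed_lags(pi - pj))))


def pli_epoch(phases: PhaseEpoch, epoch_index: int = 0) -> ConnectivityMatrix:
    """PLI over all unordered channel pairs of one epoch.

    The result is exactly symmetric (sin is odd, so swapping channels flips
    the sign inside the absolute value) with a zero diagonal.
    """
    p = np.asarray(phases.phases, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) phase array")
    # sign(sin(Δφ)) is antisymmetric in the channel pair; |mean| symmetrises it.
    diff = p[:, None, :] - p[None, :, :]
    weights = np.abs(np.mean(_signed_lags(diff), axis=-1))
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(weights=weights, band=phases.band, epoch_index=epoch_index)
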