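"""Band-pass decomposition of EEG epochs and instantaneous-phase extraction.

Resting-state epochs are analysed in five canonical frequency bands —
delta (0.5–4 Hz), theta (4–8 Hz), lower alpha (8–10 Hz), upper alpha
(10–13 Hz) and beta (13–20 Hz).  Each epoch is filtered with a zero-phase
(forward–backward) 4th-order Butterworth band-pass applied per epoch with
reflective padding of one epoch length, and the instantaneous phase is the
angle of the analytic (Hilbert) signal of the band-limited trace.

An amplitude-threshold epoch rejection utility implements the automatic
artifact criterion: an epoch is discarded as soon as any channel exceeds
the threshold (100 µV by default, configurable) at any sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "EpochSet",
    "PhaseEpoch",
    "bandpass",
    "instantaneous_phase",
    "reject_epochs",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < low < high, "
                f"got ({self.low}, {self.high})"
            )


#: The canonical five-band partition of the 0.5–20 Hz range.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("lower_alpha", 8.0, 10.0),
    BandDefinition("upper_alpha", 10.0, 13.0),
    BandDefinition("beta", 13.0, 20.0),
)


def band_by_name(name: str) -> BandDefinition:
    """Return the canonical band with the given name."""
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown canonical band {name!r}")


@dataclass
class EpochSet:
    """Artifact-free epochs for one subject at one timepoint.

    Attributes
    ----------
    data:
        Array of shape ``(n_epochs, n_channels, n_samples)``, amplitude in µV.
    sampling_rate:
        Sampling frequency in Hz.
    """

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"EpochSet.data must be (n_epochs, n_channels, n_samples), "
                f"got shape {self.data.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class PhaseEpoch:
    """Instantaneous phases (radians, wrapped to (−π, π]) of one band-limited epoch."""

    phases: np.ndarray  # (n_channels, n_samples)
    band: BandDefinition


def _validate_band_for_rate(band: BandDefinition, sampling_rate: float) -> None:
    nyquist = sampling_rate / 2.0
    if band.high >= nyquist:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz is not below the "
            f"Nyquist frequency {nyquist} Hz"
        )


def bandpass(
    epoch: np.ndarray,
    band: BandDefinition,
    sampling_rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output has no phase distortion; edge transients are controlled by
    reflective padding of (almost) one epoch length.

    Parameters
    ----------
    epoch:
        ``(..., n_samples)`` array; typically ``(n_channels, n_samples)`` or a
        whole ``(n_epochs, n_channels, n_samples)`` stack.
    band:
        Target frequency band; its upper edge must lie below Nyquist.
    sampling_rate:
        Sampling frequency in Hz.
    order:
        Butterworth order of the underlying one-way design (default 4).
    """
    x = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite samples")
    _validate_band_for_rate(band, sampling_rate)
    sos = butter(
        order, (band.low, band.high), btype="bandpass", fs=sampling_rate, output="sos"
    )
    padlen = x.shape[-1] - 1
    return sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def instantaneous_phase(
    filtered_epoch: np.ndarray, band: BandDefinition
) -> PhaseEpoch:
    """Instantaneous phase of an already band-limited epoch.

    Returns the angle of the analytic signal per channel and sample,
    wrapped to (−π, π].  The FFT-based Hilbert transform assumes a periodic
    signal, so the epoch is reflectively extended by one epoch length on
    each side before the transform (mirroring the filter's padding policy)
    and the central segment is returned; this keeps edge phase errors small.
    """
    x = np.asarray(filtered_epoch, dtype=float)
    n = x.shape[-1]
    extended = np.concatenate([x[..., ::-1], x, x[..., ::-1]], axis=-1)
    phases = np.angle(hilbert(extended, axis=-1))[..., n : 2 * n]
    return PhaseEpoch(phases=np.ascontiguousarray(phases), band=band)


def reject_epochs(epochs: EpochSet, amplitude_threshold: float) -> EpochSet:
    """Drop every epoch whose absolute amplitude exceeds the threshold anywhere.

    Parameters
    ----------
    epochs:
        Candidate epochs.
    amplitude_threshold:
        Rejection criterion in the same units as the data (µV); must be > 0.
        An epoch is retained iff ``max |x| <= threshold`` over all channels
        and samples.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = peak <= amplitude_threshold
    if not np.any(keep):
        logger.warning(
            "epoch rejection at threshold %g removed all %d epochs",
            amplitude_threshold,
            epochs.n_epochs,
        )
    return EpochSet(data=epochs.data[keep], sampling_rate=epochs.sampling_rate)
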