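"""Synthetic multichannel EEG with controllable pairwise phase-lag coupling.

There is no deposited recording behind the study cohort, so every
downstream stage is exercised on simulated data with a known ground truth.
Each channel carries a constant-amplitude narrowband oscillator,
``x(t) = cos φ(t)``, whose instantaneous frequency wanders slowly inside
the target band (a tanh-bounded, low-pass-filtered Gaussian process around
the band centre).  The constant envelope keeps the instantaneous phase
well-conditioned everywhere, so a perfectly coupled pair recovers PLI = 1
after the downstream filter/Hilbert chain.  Coupling is lagged-copy mixing:
for a coupled pair with source i, target j, lag δ and strength κ ∈ [0, 1],
the target's band component is

    x_j = κ · cos(φ_i − δ) + (1 − κ) · (independent oscillator),

so the pair's phase difference concentrates at δ as κ → 1.  δ ≡ 0 (mod π)
is rejected because the phase lag index is blind to zero-lag/antiphase
coupling.  Uncoupled channels carry independent oscillators; optional
broadband Gaussian sensor noise is added on top.

A cohort generator wraps this in the study design: a control and an MCI
group, each subject recorded at a pre-task and a post-task timepoint, with
age/education/gender covariates drawn per group.  A group×timepoint
topology effect can be injected by incrementing the coupling strength of
all pairs incident to designated hub channels in one cell of the design —
the recoverable analogue of a shift toward a star-like, hub-dominated
post-task topology in the patient group.

Note on the null level: band-limited phases are autocorrelated within an
epoch, so the finite-sample PLI of an *uncoupled* pair sits above the
i.i.d.-phase chance level ``sqrt(2/(π·n))``; the appropriate null reference
for generator output is a Monte-Carlo estimate at κ = 0 in the same band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .spectral import BandDefinition, EpochSet

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "CovariateParams",
    "CohortConfig",
    "EffectSpec",
    "CohortDataset",
    "generate_subject_epochs",
    "generate_cohort",
    "apply_effect",
]


@dataclass(frozen=True)
class CouplingEdge:
    """One coupled channel pair: lag δ (radians), strength κ, and the source.

    ``source`` names which channel of the pair drives the other; it defaults
    to the lower index when omitted at spec construction.
    """

    lag: float
    kappa: float
    source: int | None = None


@dataclass
class CouplingSpec:
    """Ground-truth pairwise coupling for one frequency band."""

    band: BandDefinition
    pairs: dict[tuple[int, int], CouplingEdge] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        canonical: dict[tuple[int, int], CouplingEdge] = {}
        targets: set[int] = set()
        for (i, j), edge in self.pairs.items():
            if i == j or i < 0 or j < 0:
                raise ValueError(f"invalid channel pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            source = edge.source if edge.source is not None else key[0]
            if source not in key:
                raise ValueError(f"source {source} not in pair {key}")
            if not 0.0 <= edge.kappa <= 1.0:
                raise ValueError(f"kappa must lie in [0, 1], got {edge.kappa}")
            if math.isclose(math.sin(edge.lag), 0.0, abs_tol=1e-9):
                raise ValueError(
                    f"lag {edge.lag} is 0 mod pi; the phase lag index cannot "
                    "detect zero-lag or antiphase coupling"
                )
            target = key[0] if source == key[1] else key[1]
            if target in targets:
                raise ValueError(f"channel {target} is the target of two pairs")
            targets.add(target)
            if key in canonical:
                raise ValueError(f"duplicate pair {key}")
            canonical[key] = CouplingEdge(lag=edge.lag, kappa=edge.kappa, source=source)
        self.pairs = canonical
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def max_channel(self) -> int:
        return max((max(k) for k in self.pairs), default=-1)

    def generation_order(self) -> list[tuple[int, int]]:
        """Pairs ordered so every source is finalized before its target."""
        by_target = {}
        for key, edge in self.pairs.items():
            target = key[0] if edge.source == key[1] else key[1]
            by_target[target] = (key, edge.source)
        order: list[tuple[int, int]] = []
        done: set[int] = set()

        def resolve(target: int, trail: set[int]) -> None:
            if target in done:
                return
            if target in trail:
                raise ValueError("coupling pairs form a cycle")
            trail.add(target)
            key, source = by_target[target]
            if source in by_target:
                resolve(source, trail)
            order.append(key)
            done.add(target)

        for target in sorted(by_target):
            resolve(target, set())
        return order


@dataclass(frozen=True)
class CovariateParams:
    """Per-group covariate distributions (normal age/education, Bernoulli gender)."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_proportion: float

    def __post_init__(self) -> None:
        if self.age_sd < 0 or self.education_sd < 0:
            raise ValueError("covariate SDs must be nonnegative")
        if not 0.0 <= self.female_proportion <= 1.0:
            raise ValueError("female_proportion must lie in [0, 1]")


#: Default covariate distributions matching the study cohort's demographics.
DEFAULT_COVARIATES: dict[str, CovariateParams] = {
    "control": CovariateParams(71.10, 6.18, 15.26, 2.34, 0.91),
    "MCI": CovariateParams(73.73, 7.19, 14.46, 2.42, 0.85),
}


@dataclass
class CohortConfig:
    """Design of a simulated pre/post two-group EEG cohort."""

    n_control: int = 58
    n_mci: int = 41
    n_epochs_per_subject: int = 30
    n_channels: int = 64
    epoch_samples: int = 1024
    sampling_rate: float = 500.0
    covariate_params: Mapping[str, CovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_control", self.n_control),
            ("n_mci", self.n_mci),
            ("n_epochs_per_subject", self.n_epochs_per_subject),
            ("n_channels", self.n_channels),
            ("epoch_samples", self.epoch_samples),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if set(self.covariate_params) != {"control", "MCI"}:
            raise ValueError("covariate_params must have 'control' and 'MCI' entries")


@dataclass(frozen=True)
class EffectSpec:
    """A group×timepoint coupling increment on hub-incident pairs.

    In the targeted design cell, for every hub channel h and every other
    channel c the pair {h, c} (source h) has its coupling strength raised by
    ``coupling_increment`` (created at that strength with lag ``lag`` when
    absent; an existing pair targeting c from elsewhere is replaced).  A
    large increment drives the band's maximum spanning tree toward a star
    centred on the hub.
    """

    target_group: str = "MCI"
    target_timepoint: str = "post"
    hub_channels: tuple[int, ...] = (0,)
    coupling_increment: float = 0.5
    lag: float = math.pi / 4
    bands: tuple[str, ...] | None = None  # None = every band

    def __post_init__(self) -> None:
        if self.coupling_increment < 0:
            raise ValueError("coupling_increment must be >= 0")
        if not self.hub_channels:
            raise ValueError("need at least one hub channel")


def apply_effect(spec: CouplingSpec, effect: EffectSpec, n_channels: int) -> CouplingSpec:
    """Return a copy of ``spec`` with the hub increment applied."""
    if effect.bands is not None and spec.band.name not in effect.bands:
        return spec
    pairs = dict(spec.pairs)
    target_of: dict[int, tuple[int, int]] = {}
    for key, edge in pairs.items():
        target = key[0] if edge.source == key[1] else key[1]
        target_of[target] = key
    claimed: set[int] = set()
    for hub in effect.hub_channels:
        if not 0 <= hub < n_channels:
            raise ValueError(f"hub channel {hub} out of range")
        for c in range(n_channels):
            if c == hub or c in claimed or c in effect.hub_channels:
                continue
            key = (min(hub, c), max(hub, c))
            old = pairs.get(key)
            if old is not None and old.source == hub:
                kappa = old.kappa + effect.coupling_increment
                lag = old.lag
            else:
                # hub takes precedence over a background pair driving c
                if c in target_of and target_of[c] != key:
                    pairs.pop(target_of[c])
                elif old is not None:
                    pairs.pop(key)
                kappa = effect.coupling_increment
                lag = effect.lag
            if kappa > 1.0 + 1e-12:
                raise ValueError(
                    f"coupling increment pushes kappa to {kappa} > 1 on pair {key}"
                )
            pairs[key] = CouplingEdge(lag=lag, kappa=min(kappa, 1.0), source=hub)
            claimed.add(c)
    return CouplingSpec(band=spec.band, pairs=pairs, noise_sd=spec.noise_sd)


#: Fraction of the half-bandwidth the instantaneous frequency may wander.
_FREQ_EXCURSION = 0.6
#: Upper cutoff (Hz) for the frequency-wander process (slower than any band).
_WANDER_CUTOFF = 2.0


def _oscillator_phases(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    band: BandDefinition,
    fs: float,
) -> np.ndarray:
    """Phase trajectories of independent frequency-wandering oscillators.

    Per channel, the instantaneous frequency is the band centre plus a
    tanh-bounded low-pass-filtered Gaussian excursion covering at most
    ``_FREQ_EXCURSION`` of the half-bandwidth; the phase is its cumulative
    integral with a uniform random start.
    """
    f_mid = (band.low + band.high) / 2.0
    half = (band.high - band.low) / 2.0
    cutoff = min(half, _WANDER_CUTOFF)
    sos = butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    g = sosfiltfilt(
        sos,
        rng.standard_normal((n_channels, n_samples)),
        axis=-1,
        padtype="even",
        padlen=n_samples - 1,
    )
    rms = np.sqrt(np.mean(g**2, axis=-1, keepdims=True))
    g = g / np.maximum(rms, 1e-12)
    freq = f_mid + _FREQ_EXCURSION * half * np.tanh(g)
    phi0 = rng.uniform(-math.pi, math.pi, size=(n_channels, 1))
    return phi0 + 2.0 * math.pi * np.cumsum(freq, axis=-1) / fs


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate a narrowband signal's analytic phase backward by ``lag`` radians."""
    return np.real(hilbert(x, axis=-1) * np.exp(-1j * lag))


def generate_subject_epochs(
    spec: CouplingSpec,
    n_epochs: int,
    epoch_samples: int,
    sampling_rate: float,
    seed: int | np.random.SeedSequence,
    n_channels: int = 64,
) -> EpochSet:
    """Simulate one subject-timepoint recording in one band.

    Every channel starts as an independent constant-amplitude oscillator
    inside the band; coupled targets are replaced by the κ-weighted
    lagged-copy mixture (the shift is exact where the source's phase
    trajectory is known, analytic-signal rotation otherwise), and broadband
    Gaussian noise of SD ``spec.noise_sd`` is added throughout.  Identical
    arguments (including the seed) give bit-identical output.
    """
    if n_epochs < 1 or epoch_samples < 2:
        raise ValueError("need n_epochs >= 1 and epoch_samples >= 2")
    if spec.max_channel() >= n_channels:
        raise ValueError("coupling spec references channels beyond n_channels")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    order = spec.generation_order()
    data = np.empty((n_epochs, n_channels, epoch_samples))
    for e in range(n_epochs):
        phases = _oscillator_phases(
            rng, n_channels, epoch_samples, spec.band, sampling_rate
        )
        signals = np.cos(phases)
        # channels whose exact phase trajectory is known (all, initially)
        known: dict[int, np.ndarray] = {ch: phases[ch] for ch in range(n_channels)}
        for key in order:
            edge = spec.pairs[key]
            source = edge.source
            target = key[0] if source == key[1] else key[1]
            src_phase = known.get(source)
            if src_phase is not None:
                shifted = np.cos(src_phase - edge.lag)
            else:
                shifted = _phase_shift(signals[source], edge.lag)
            signals[target] = edge.kappa * shifted + (1.0 - edge.kappa) * np.cos(
                phases[target]
            )
            if edge.kappa == 1.0 and src_phase is not None:
                known[target] = src_phase - edge.lag
            else:
                known.pop(target, None)
        if spec.noise_sd > 0:
            signals = signals + spec.noise_sd * rng.standard_normal(signals.shape)
        data[e] = signals
    return EpochSet(data=data, sampling_rate=sampling_rate)


def _subject_seed(config_seed: int, subject_index: int, tp_index: int, band_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([config_seed, subject_index, tp_index, band_index])


@dataclass
class CohortDataset:
    """A simulated cohort: eager metadata, lazily generated epochs.

    ``subject_epochs`` regenerates a subject-timepoint recording on demand
    from seeds derived deterministically from the cohort seed, so the full
    dataset never has to sit in memory and identical configurations always
    yield identical data.
    """

    config: CohortConfig
    metadata: pd.DataFrame
    base_specs: dict[str, CouplingSpec]
    effect: EffectSpec | None = None

    TIMEPOINTS = ("pre", "post")

    def _spec_for(self, band_name: str, group: str, timepoint: str) -> CouplingSpec:
        spec = self.base_specs[band_name]
        if (
            self.effect is not None
            and group == self.effect.target_group
            and timepoint == self.effect.target_timepoint
        ):
            spec = apply_effect(spec, self.effect, self.config.n_channels)
        return spec

    def subject_epochs(self, subject: str, timepoint: str) -> EpochSet:
        """Broadband epochs (sum of per-band components) for one recording."""
        if timepoint not in self.TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        row = self.metadata.loc[self.metadata["subject"] == subject]
        if row.empty:
            raise KeyError(f"unknown subject {subject!r}")
        group = row["group"].iloc[0]
        s_idx = int(row.index[0])
        t_idx = self.TIMEPOINTS.index(timepoint)
        cfg = self.config
        total = np.zeros((cfg.n_epochs_per_subject, cfg.n_channels, cfg.epoch_samples))
        for b_idx, (band_name, _) in enumerate(sorted(self.base_specs.items())):
            spec = self._spec_for(band_name, group, timepoint)
            component = generate_subject_epochs(
                spec,
                n_epochs=cfg.n_epochs_per_subject,
                epoch_samples=cfg.epoch_samples,
                sampling_rate=cfg.sampling_rate,
                seed=_subject_seed(cfg.seed, s_idx, t_idx, b_idx),
                n_channels=cfg.n_channels,
            )
            total += component.data
        return EpochSet(data=total, sampling_rate=cfg.sampling_rate)

    def iter_recordings(self):
        """Yield (subject, group, timepoint, EpochSet) over the whole design."""
        for subject, group in zip(self.metadata["subject"], self.metadata["group"]):
            for timepoint in self.TIMEPOINTS:
                yield subject, group, timepoint, self.subject_epochs(subject, timepoint)


def _draw_covariates(
    rng: np.random.Generator, params: CovariateParams, n: int
) -> pd.DataFrame:
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    education = rng.normal(params.education_mean, params.education_sd, size=n)
    female = rng.random(n) < params.female_proportion
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "gender": np.where(female, "female", "male"),
            "education": np.round(education, 1),
        }
    )


def generate_cohort(
    config: CohortConfig,
    base_specs: Mapping[str, CouplingSpec] | CouplingSpec,
    effect: EffectSpec | None = None,
) -> CohortDataset:
    """Simulate the cohort design: metadata now, per-recording epochs lazily.

    ``base_specs`` maps band names to coupling specifications (a single spec
    is accepted for single-band studies).  With ``effect=None`` the two
    groups are exchangeable by construction: group labels influence nothing
    but the covariate draws.
    """
    if isinstance(base_specs, CouplingSpec):
        base_specs = {base_specs.band.name: base_specs}
    specs = dict(base_specs)
    for name, spec in specs.items():
        if spec.max_channel() >= config.n_channels:
            raise ValueError(f"spec for band {name!r} references out-of-range channels")
        if effect is not None:
            apply_effect(spec, effect, config.n_channels)  # validate increments now

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    frames = []
    for group, n in (("control", config.n_control), ("MCI", config.n_mci)):
        cov = _draw_covariates(rng, config.covariate_params[group], n)
        cov.insert(0, "group", group)
        frames.append(cov)
    metadata = pd.concat(frames, ignore_index=True)
    metadata.insert(
        0, "subject", [f"S{k:03d}" for k in range(len(metadata))]
    )
    return CohortDataset(
        config=config, metadata=metadata, base_specs=specs, effect=effect
    )
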