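"""Synthetic two-class motor-imagery EEG generators.

The generators emulate the statistical structure that spatial-filter
pipelines exploit in sensorimotor EEG: narrowband oscillatory sources whose
band power is attenuated or enhanced depending on the imagined task
(ERD/ERS), linearly mixed into the channel array together with spatially
correlated broadband noise.  They produce pre-epoched trial stacks (or,
optionally, a continuous record with cue times) that exercise every stage
of the pipeline without any recorded data.

Three generators are provided:

``generate_trials``
    Class-dependent spatial covariance: each discriminative source's
    amplitude is scaled by ``(1 + delta)`` for one class and ``(1 - delta)``
    for the other, with successive sources modulated in opposite directions.
``generate_null_trials``
    The identical process with ``delta = 0`` and randomly assigned labels;
    any classifier should be at chance.
``generate_planted_lag_trials``
    Classes differ only in the sign of a lagged echo of a broadband source,
    so instantaneous spatial covariance carries no class information and the
    discriminative structure appears only under delay embedding at the
    planted lag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .containers import TrialSet

__all__ = [
    "SimConfig",
    "generate_trials",
    "generate_null_trials",
    "generate_planted_lag_trials",
    "generate_continuous_record",
    "delta_from_snr",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    n_trials_per_class : int
        Trials per class (>= 2); total trials are twice this.
    n_channels : int
        Number of EEG channels C (>= 2).
    fs : float
        Sampling rate in Hz; must exceed twice the upper signal-band edge.
    duration_s : float
        Trial length in seconds; ``duration_s * fs`` must be an integer.
    signal_band : tuple of float
        (low, high) Hz of the discriminative oscillations; default (10, 13),
        the mu-rhythm range.
    snr : float
        Linear ratio of total discriminative-source variance to per-channel
        noise variance.  Also sets the class amplitude asymmetry ``delta``
        (see :func:`delta_from_snr`); ``snr = 0`` makes the two classes
        identically distributed.
    n_discriminative_sources : int
        Number of class-modulated sources (default 2).
    seed : int
        Seed of the single random generator used for everything.
    pink_noise : bool
        If True the background noise has a 1/f amplitude spectrum instead
        of white.
    """

    n_trials_per_class: int = 100
    n_channels: int = 10
    fs: float = 100.0
    duration_s: float = 3.0
    signal_band: tuple[float, float] = (10.0, 13.0)
    snr: float = 1.0
    n_discriminative_sources: int = 2
    seed: int = 0
    pink_noise: bool = False

    def validate(self) -> None:
        low, high = self.signal_band
        if self.n_trials_per_class < 2:
            raise ValueError("n_trials_per_class must be >= 2")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not 0 < low < high:
            raise ValueError("signal_band must satisfy 0 < low < high")
        if self.fs <= 2 * high:
            raise ValueError("fs must exceed twice the upper band edge")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9 or round(n) < 16:
            raise ValueError("duration_s * fs must be an integer >= 16")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_discriminative_sources < 1:
            raise ValueError("n_discriminative_sources must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def delta_from_snr(snr: float) -> float:
    """Class amplitude asymmetry from the signal-to-noise ratio.

    ``delta`` is chosen so the ratio of class band-power variances at a
    boosted pattern equals ``1 + snr``:

        ((1 + delta) / (1 - delta))**2 = 1 + snr
        delta = (sqrt(1 + snr) - 1) / (sqrt(1 + snr) + 1)

    ``snr = 0`` gives ``delta = 0`` (no class difference).
    """
    root = np.sqrt(1.0 + snr)
    return (root - 1.0) / (root + 1.0)


def _mixing_matrix(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    """Random orthonormal mixing matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    # fix gauge so the matrix is a deterministic function of the draw
    q *= np.sign(np.diag(r))
    return q


def _background_noise(
    rng: np.random.Generator, cfg: SimConfig, n_trials: int
) -> np.ndarray:
    """Unit-variance per-channel noise, (n_trials, C, T), before mixing."""
    shape = (n_trials, cfg.n_channels, cfg.n_samples)
    noise = rng.standard_normal(shape)
    if cfg.pink_noise:
        spec = np.fft.rfft(noise, axis=-1)
        freqs = np.fft.rfftfreq(cfg.n_samples, d=1.0 / cfg.fs)
        scale = np.ones_like(freqs)
        nonzero = freqs > 0
        scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
        spec *= scale
        noise = np.fft.irfft(spec, n=cfg.n_samples, axis=-1)
        noise /= noise.std(axis=-1, keepdims=True)
    return noise


def _labels(rng: np.random.Generator, n_per_class: int) -> np.ndarray:
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=np.int64), -np.ones(n_per_class, dtype=np.int64)]
    )
    rng.shuffle(labels)
    return labels


def _oscillatory_trials(
    cfg: SimConfig, delta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Core generative process shared by the class-modulated and null sets."""
    n_total = 2 * cfg.n_trials_per_class
    T = cfg.n_samples
    K = cfg.n_discriminative_sources

    mixing = _mixing_matrix(rng, cfg.n_channels)
    labels = _labels(rng, cfg.n_trials_per_class)

    low, high = cfg.signal_band
    # fixed source frequencies spread across the band
    freqs = low + (np.arange(1, K + 1) / (K + 1)) * (high - low)
    # per-source variance so the total source variance is snr x noise variance
    amp = np.sqrt(2.0 * cfg.snr / K) if cfg.snr > 0 else 0.0

    t = np.arange(T) / cfg.fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_total, K))
    # alternate the direction of class modulation across sources
    directions = np.where(np.arange(K) % 2 == 0, 1.0, -1.0)
    gains = 1.0 + delta * directions[None, :] * labels[:, None]  # (n_total, K)

    waves = amp * gains[:, :, None] * np.sin(
        2.0 * np.pi * freqs[None, :, None] * t[None, None, :]
        + phases[:, :, None]
    )  # (n_total, K, T)

    noise = _background_noise(rng, cfg, n_total)
    data = np.einsum("cd,ndt->nct", mixing, noise)
    patterns = mixing[:, :K]  # source k projects onto column k
    data += np.einsum("ck,nkt->nct", patterns, waves)

    internals = {
        "mixing": mixing,
        "patterns": patterns,
        "source_freqs": freqs,
        "source_waves": waves,
        "delta": delta,
        "gains": gains,
    }
    return data, labels, internals


def generate_trials(
    cfg: SimConfig, return_internals: bool = False
) -> TrialSet | tuple[TrialSet, dict]:
    """Generate a balanced two-class trial set with ERD-like structure.

    Class +1 boosts even-indexed sources by ``(1 + delta)`` and attenuates
    odd-indexed ones by ``(1 - delta)``; class -1 does the opposite.  The
    same seed yields bit-identical output.

    With ``return_internals=True`` also returns the mixing matrix, the
    spatial patterns, and the pre-mixing source waveforms, for direct
    verification of the planted band-power effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    delta = delta_from_snr(cfg.snr)
    data, labels, internals = _oscillatory_trials(cfg, delta, rng)
    ts = TrialSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        meta={"generator": "oscillatory", "seed": cfg.seed, "snr": cfg.snr,
              "delta": delta},
    )
    return (ts, internals) if return_internals else ts


def generate_null_trials(
    cfg: SimConfig, return_internals: bool = False
) -> TrialSet | tuple[TrialSet, dict]:
    """Generate trials whose two classes share one distribution.

    The generative process is identical for both classes (``delta = 0``;
    the oscillatory sources are still present at the configured ``snr``)
    and labels are assigned at random, so any downstream classifier should
    perform at chance level.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    data, labels, internals = _oscillatory_trials(cfg, 0.0, rng)
    ts = TrialSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        meta={"generator": "null", "seed": cfg.seed, "snr": cfg.snr},
    )
    return (ts, internals) if return_internals else ts


def generate_planted_lag_trials(
    cfg: SimConfig,
    lag: int,
    echo_gain: float = 0.9,
    band: tuple[float, float] = (7.0, 30.0),
) -> TrialSet:
    """Generate trials whose class difference lives at a planted lag.

    A broadband band-limited source ``s`` is combined with a lagged echo
    whose sign depends on the class::

        x(t) = s(t) + y * echo_gain * s(t - lag),   y in {+1, -1}

    Both classes then have the same instantaneous spatial covariance (the
    echo contributes ``echo_gain**2 * var(s)`` regardless of sign), but the
    lagged cross-covariance at delay ``lag`` differs in sign between
    classes.  Only delay embedding at (or near) the planted lag exposes the
    class structure, which makes this set a ground truth for the
    cross-validated selection of the embedding delay.
    """
    cfg.validate()
    if lag < 1 or lag >= cfg.n_samples // 2:
        raise ValueError("lag must be in [1, n_samples/2)")
    rng = np.random.default_rng(cfg.seed)
    n_total = 2 * cfg.n_trials_per_class
    T = cfg.n_samples

    mixing = _mixing_matrix(rng, cfg.n_channels)
    labels = _labels(rng, cfg.n_trials_per_class)

    # broadband band-limited source: its autocorrelation decays within a few
    # samples, so the echo is detectable only at the planted lag
    sos = _signal.butter(4, band, btype="bandpass", fs=cfg.fs, output="sos")
    pad = 4 * lag + 64
    raw = rng.standard_normal((n_total, T + lag + 2 * pad))
    s = _signal.sosfiltfilt(sos, raw, axis=-1)[:, pad:-pad]
    s /= s.std(axis=-1, keepdims=True)

    main = s[:, lag:lag + T]
    echo = s[:, :T]
    combined = main + echo_gain * labels[:, None] * echo
    scale = np.sqrt(cfg.snr / (1.0 + echo_gain**2)) if cfg.snr > 0 else 0.0
    combined *= scale

    noise = _background_noise(rng, cfg, n_total)
    data = np.einsum("cd,ndt->nct", mixing, noise)
    data += mixing[:, [0]][None, :, :] * combined[:, None, :]

    return TrialSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        meta={"generator": "planted_lag", "seed": cfg.seed, "lag": lag,
              "snr": cfg.snr},
    )


def generate_continuous_record(
    cfg: SimConfig, gap_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Emit one continuous record with cue times, to exercise epoching.

    Trials from :func:`generate_trials` are laid head-to-tail with
    noise-only gaps of ``gap_s`` seconds between them.  Returns
    ``(record, cue_samples, labels, fs)`` where ``record`` is C x N and
    ``cue_samples[i]`` is the 0-based sample index at which trial ``i``
    starts.
    """
    trials = generate_trials(cfg)
    gap = int(round(gap_s * cfg.fs))
    rng = np.random.default_rng(cfg.seed + 1)
    n, C, T = trials.data.shape
    N = n * (T + gap) + gap
    record = rng.standard_normal((C, N))
    cues = np.empty(n, dtype=np.int64)
    for i in range(n):
        start = gap + i * (T + gap)
        record[:, start:start + T] = trials.data[i]
        cues[i] = start
    return record, cues, trials.labels, cfg.fs
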