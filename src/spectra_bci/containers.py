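"""In-memory container for a set of labelled EEG trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialSet:
    """A stack of single-trial multichannel EEG epochs with binary labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial signals in microvolts (or arbitrary consistent units).
    labels : ndarray, shape (n_trials,)
        Class labels, +1 (e.g. right-hand motor imagery) or -1.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One name per channel; generated as ``ch00..`` if omitted.
    meta : dict
        Free-form provenance (generator seed, preprocessing applied, ...).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples), got {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise ValueError("empty trial set")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "TrialSet":
        """Return a new TrialSet restricted to trial indices ``idx``."""
        idx = np.asarray(idx)
        return TrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )
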