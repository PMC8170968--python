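"""Common average referencing, Butterworth band-pass filtering, epoching.

The preprocessing protocol mirrors standard motor-imagery practice: each
trial is re-referenced to the common average, band-pass filtered with a
Butterworth filter over a single wide 7-30 Hz band, and (for continuous
recordings) cut into cue-aligned epochs, by default 0.5-2.5 s after the cue.
Filtering is applied forward-backward (zero phase) so epochs are not
phase-shifted relative to the cue; the filter order defaults to 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .containers import TrialSet

__all__ = [
    "FilterSpec",
    "common_average_reference",
    "bandpass",
    "extract_epoch",
    "extract_epochs",
    "preprocess_trials",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``low``/``high`` in Hz, ``order`` the filter order (>= 1); with
    ``zero_phase`` the filter runs forward and backward (``sosfiltfilt``),
    doubling the effective order and cancelling group delay.
    """

    low: float = 7.0
    high: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.high >= fs / 2:
            raise ValueError(
                f"band edge {self.high} Hz at or above Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every sample.

    Accepts a single trial (C x T) or a trial stack (n x C x T); the
    channel axis is the second-to-last.  After CAR each sample's channel
    sum is zero; applying CAR twice changes nothing.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim < 2:
        raise ValueError("expected at least 2-D (channels x samples)")
    if data.shape[-2] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return data - data.mean(axis=-2, keepdims=True)


def bandpass(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth band-pass along the last (time) axis."""
    data = np.asarray(data, dtype=np.float64)
    spec.validate(fs)
    T = data.shape[-1]
    if T <= 3 * spec.order:
        raise ValueError(f"need more than {3 * spec.order} samples, got {T}")
    sos = _signal.butter(
        spec.order, (spec.low, spec.high), btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return _signal.sosfiltfilt(sos, data, axis=-1)
    return _signal.sosfilt(sos, data, axis=-1)


def extract_epoch(
    record: np.ndarray,
    fs: float,
    cue_sample: int,
    window: tuple[float, float] = (0.5, 2.5),
    trial_id: int | str | None = None,
) -> np.ndarray:
    """Cut one cue-aligned epoch out of a continuous C x N record.

    Returns samples ``[cue + round(t_start*fs), cue + round(t_end*fs))``
    (half-open, 0-based).  At ``fs = 100`` the default 0.5-2.5 s window
    yields 200 samples; at ``fs = 250`` it yields 500.
    """
    record = np.asarray(record)
    if record.ndim != 2:
        raise ValueError("record must be 2-D (channels x samples)")
    t_start, t_end = window
    start = cue_sample + int(round(t_start * fs))
    stop = cue_sample + int(round(t_end * fs))
    tag = "" if trial_id is None else f" (trial {trial_id})"
    if stop <= start:
        raise ValueError(f"empty epoch window {window}{tag}")
    if start < 0 or stop > record.shape[1]:
        raise ValueError(
            f"epoch [{start}, {stop}) exceeds record of "
            f"{record.shape[1]} samples{tag}"
        )
    return record[:, start:stop]


def extract_epochs(
    record: np.ndarray,
    fs: float,
    cue_samples: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float] = (0.5, 2.5),
) -> TrialSet:
    """Epoch a continuous record at every cue and stack into a TrialSet."""
    epochs = [
        extract_epoch(record, fs, int(c), window, trial_id=i)
        for i, c in enumerate(cue_samples)
    ]
    return TrialSet(data=np.stack(epochs), labels=np.asarray(labels), fs=fs)


def preprocess_trials(
    trials: TrialSet,
    spec: FilterSpec = FilterSpec(),
    epoch_window: tuple[float, float] | None = None,
) -> TrialSet:
    """CAR then band-pass each trial; optionally crop to a sub-window.

    For pre-epoched data ``epoch_window`` is interpreted relative to the
    trial start (e.g. (0.5, 2.5) keeps samples 50..249 at 100 Hz).  The
    crop happens after filtering so filter transients fall outside the
    analysis window.
    """
    data = common_average_reference(trials.data)
    data = bandpass(data, trials.fs, spec)
    if epoch_window is not None:
        t_start, t_end = epoch_window
        start = int(round(t_start * trials.fs))
        stop = int(round(t_end * trials.fs))
        if stop <= start or start < 0 or stop > data.shape[-1]:
            raise ValueError(
                f"epoch window {epoch_window} invalid for trials of "
                f"{data.shape[-1]} samples"
            )
        data = data[..., start:stop]
    meta = dict(trials.meta)
    meta["preprocessed"] = {
        "car": True,
        "band": (spec.low, spec.high),
        "order": spec.order,
        "zero_phase": spec.zero_phase,
        "epoch_window": epoch_window,
    }
    return TrialSet(
        data=data,
        labels=trials.labels,
        fs=trials.fs,
        channel_names=list(trials.channel_names),
        meta=meta,
    )
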