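"""Signal conditioning and interval → per-sample label conversion.

Conditioning is a zero-phase Fourier filter: FFT, zero every bin strictly
below 0.5 Hz or strictly above 45 Hz, inverse FFT.  This removes drift and
mains/EMG residue while leaving the alpha (8–12 Hz) and theta (4–7 Hz)
bands — the carriers of the wake/microsleep distinction — untouched.  All
channels (EEG and EOG) are filtered identically, over the whole recording,
before any windowing.

Two input scalings are provided, matching the two network families:
``scale_cnn`` maps μV to [−1, 1] via x/100, ``scale_lstm`` maps to [0, 1]
via (x+100)/200; both clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, IntervalError
from .io import Event, EventList, Recording
from .labels import Label

__all__ = [
    "BandpassSpec",
    "LabelTrack",
    "fourier_bandpass",
    "filter_recording",
    "scale_cnn",
    "scale_lstm",
    "rasterize_events",
    "extract_runs",
    "seconds_to_sample",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Passband edges in Hz; bins at exactly lo/hi are retained."""

    lo_hz: float = 0.5
    hi_hz: float = 45.0

    def validate(self, fs: float) -> None:
        if not 0 < self.lo_hz < self.hi_hz < fs / 2:
            raise DataError(
                f"need 0 < lo < hi < fs/2, got lo={self.lo_hz}, hi={self.hi_hz}, fs={fs}"
            )


@dataclass
class LabelTrack:
    """One integer class code per signal sample."""

    labels: np.ndarray  # shape (n_samples,), values in TRACK_CLASSES
    fs: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise DataError("label track must be one-dimensional")

    def __len__(self) -> int:
        return len(self.labels)


def fourier_bandpass(
    x: np.ndarray, fs: float, spec: BandpassSpec = BandpassSpec()
) -> np.ndarray:
    """Zero-phase bandpass by zeroing FFT bins outside [lo_hz, hi_hz].

    Operates on the last axis, so a whole channels × samples matrix can be
    filtered in one call.  Idempotent: the retained bins are passed through
    bit-exactly up to FFT round-off.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise DataError("need at least 2 samples to filter")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite samples in input")
    spec.validate(fs)
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    spectrum = np.fft.rfft(x, axis=-1)
    keep = (freqs >= spec.lo_hz) & (freqs <= spec.hi_hz)
    spectrum = np.where(keep, spectrum, 0.0)
    return np.fft.irfft(spectrum, n=x.shape[-1], axis=-1)


def filter_recording(
    recording: Recording, spec: BandpassSpec = BandpassSpec()
) -> Recording:
    """Return a new recording with every channel bandpass-filtered."""
    return Recording(
        id=recording.id,
        fs=recording.fs,
        channels=list(recording.channels),
        data=fourier_bandpass(recording.data, recording.fs, spec),
    )


def scale_cnn(x: np.ndarray) -> np.ndarray:
    """μV → dimensionless input for the CNNs: clip(x / 100, −1, 1)."""
    return np.clip(np.asarray(x, dtype=float) / 100.0, -1.0, 1.0)


def scale_lstm(x: np.ndarray) -> np.ndarray:
    """μV → dimensionless input for the CNN-LSTM: clip((x + 100) / 200, 0, 1)."""
    return np.clip((np.asarray(x, dtype=float) + 100.0) / 200.0, 0.0, 1.0)


def seconds_to_sample(t: float, fs: int) -> int:
    """floor(t·fs) with a 1e-6-sample guard against binary-float droop.

    Times that are exact multiples of 1/fs (every scored boundary is) would
    otherwise occasionally land one sample early, e.g. 36.66·200 evaluates
    to 7331.999999999999.
    """
    return int(np.floor(t * fs + 1e-6))


def rasterize_events(
    events: EventList,
    n_samples: int,
    fs: int,
    sleep_as: Label = Label.MSE,
) -> LabelTrack:
    """Convert interval scorings to one label per sample.

    Seconds map to the sample grid as floor(start·fs) inclusive to
    floor(end·fs) exclusive; unscored samples are wake.  SLEEP episodes
    (consolidated sleep > 15 s) are mapped to ``sleep_as`` (default MSE, the
    convention used for training targets).
    """
    labels = np.full(n_samples, int(Label.W), dtype=np.int64)
    for ev in events:
        i = seconds_to_sample(ev.start_s, fs)
        j = seconds_to_sample(ev.end_s, fs)
        if j > n_samples:
            raise IntervalError(
                f"event [{ev.start_s}, {ev.end_s}) s exceeds the {n_samples}-sample track"
            )
        lab = sleep_as if ev.label is Label.SLEEP else ev.label
        labels[i:j] = int(lab)
    return LabelTrack(labels=labels, fs=fs)


def extract_runs(track: LabelTrack) -> EventList:
    """Inverse of rasterization: maximal non-wake runs become events.

    Event boundaries land exactly on the sample grid, so
    ``rasterize_events(extract_runs(t))`` restores ``t`` sample-exactly.
    """
    labels = track.labels
    n = len(labels)
    events: list[Event] = []
    if n:
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for i, j in zip(starts, ends):
            lab = Label(int(labels[i]))
            if lab is not Label.W:
                events.append(Event(start_s=i / track.fs, end_s=j / track.fs, label=lab))
    return EventList(events=events, total_duration_s=n / track.fs)
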