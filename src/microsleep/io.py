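"""Signal and scoring I/O: EDF recordings and CSV event lists.

The in-memory model is deliberately small:

* :class:`Recording` — a channels × samples matrix of amplitudes in μV at a
  single sampling rate (clinical montages here are derivations such as
  ``O1M2`` = O1 − M2, occipital EEG referenced to the contralateral mastoid,
  and the two EOG derivations ``E1M1``/``E2M1``).
* :class:`Event` / :class:`EventList` — half-open scored intervals in
  seconds, non-overlapping, covering wake/MSE/MSEc/ED/SLEEP.

Signals travel as EDF (the export format of clinical polysomnographs);
scorings as a minimal CSV dialect ``label,start_s,end_s`` with a pluggable
parser hook for foreign scoring layouts.  Reading EDF goes through MNE;
writing uses a self-contained 16-bit EDF encoder, so a write→read round
trip crosses two independent codecs and must agree within the 16-bit
quantization of the declared physical range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import (
    ChannelError,
    DataError,
    EventOverlapError,
    FormatError,
    IntervalError,
    RateMismatchError,
)
from .labels import Label, parse_label

__all__ = [
    "Recording",
    "Event",
    "EventList",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

# Default physical range of the 16-bit EDF encoding, in μV.  ±3276.8 gives a
# quantization step of 0.1 μV, far below EEG noise floors.
PHYS_MIN_UV = -3276.8
PHYS_MAX_UV = 3276.8
_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """A multichannel electrophysiological recording in μV."""

    id: str
    fs: int
    channels: list[str]
    data: np.ndarray  # shape (n_channels, n_samples), float, μV

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("recording data must be a channels × samples matrix")
        if len(self.channels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} rows"
            )
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise ChannelError(
                f"channel {name!r} not in recording (has {self.channels})"
            ) from None


@dataclass(frozen=True, order=True)
class Event:
    """One scored episode, half-open in seconds: [start_s, end_s)."""

    start_s: float
    end_s: float
    label: Label

    def __post_init__(self) -> None:
        if self.start_s < 0 or not self.end_s > self.start_s:
            raise IntervalError(
                f"invalid interval [{self.start_s}, {self.end_s}) for {self.label.name}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventList:
    """Sorted, non-overlapping scored events over [0, total_duration_s]."""

    events: list[Event] = field(default_factory=list)
    total_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        offending = [
            (a, b)
            for a, b in zip(self.events, self.events[1:])
            if b.start_s < a.end_s
        ]
        if offending:
            pairs = "; ".join(
                f"[{a.start_s},{a.end_s}) {a.label.name} vs "
                f"[{b.start_s},{b.end_s}) {b.label.name}"
                for a, b in offending
            )
            raise EventOverlapError(f"overlapping events: {pairs}")
        if self.total_duration_s is None:
            self.total_duration_s = max((e.end_s for e in self.events), default=0.0)
        elif self.events and self.events[-1].end_s > self.total_duration_s + 1e-9:
            raise IntervalError(
                f"event ends at {self.events[-1].end_s} s beyond the stated "
                f"duration {self.total_duration_s} s"
            )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return self.events == other.events


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_header_fields(path: Path) -> tuple[int, list[int]]:
    """Return (n_signals, samples-per-record per signal) from a raw EDF header.

    Used only to detect mixed per-channel sampling rates, which MNE would
    silently upsample.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: not an EDF file ({exc})") from exc
        per_sig = fh.read(256 * ns)
        if len(per_sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal headers")
        off = 216 * ns  # nr-of-samples field follows 216 bytes of per-signal text
        nsamps = [
            int(per_sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
            for i in range(ns)
        ]
    return ns, nsamps


def read_recording(
    path: str | Path,
    channel_map: dict[str, tuple[str, str | None]] | None = None,
    expected_fs: int | None = None,
    id: str | None = None,
) -> Recording:
    """Read an EDF/EDF+ file and assemble the requested derivations.

    Parameters
    ----------
    path
        EDF file to read.
    channel_map
        Mapping ``derivation_name -> (signal, reference)``; the derivation is
        computed samplewise as ``signal − reference``.  A reference of ``None``
        passes the signal channel through unchanged.  If omitted, every channel
        in the file is taken as-is.
    expected_fs
        If given, reading fails (rather than resampling) when the file's
        sampling rate differs.

    Returns
    -------
    Recording
        Amplitudes in μV, channels in the order of ``channel_map``.
    """
    import mne

    path = Path(path)
    try:
        ns, nsamps = _edf_header_fields(path)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(set(nsamps)) > 1:
        raise RateMismatchError(
            f"{path}: channels have mixed sampling rates (samples/record {sorted(set(nsamps))})"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises plain ValueError/OSError on bad files
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc

    fs = int(round(raw.info["sfreq"]))
    if expected_fs is not None and fs != expected_fs:
        raise RateMismatchError(
            f"{path}: sampling rate {fs} Hz differs from expected {expected_fs} Hz"
        )
    names = raw.ch_names
    data_uv = raw.get_data() * 1e6  # MNE holds EEG/EOG in volts

    def trace(name: str) -> np.ndarray:
        if name not in names:
            raise ChannelError(f"{path}: no channel {name!r} (file has {names})")
        return data_uv[names.index(name)]

    if channel_map is None:
        out_names = list(names)
        out = data_uv
    else:
        out_names = list(channel_map)
        rows = []
        for deriv, (sig, ref) in channel_map.items():
            x = trace(sig)
            if ref is not None:
                x = x - trace(ref)
            rows.append(x)
        out = np.vstack(rows)
    return Recording(id=id or path.stem, fs=fs, channels=out_names, data=out)


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_recording(
    recording: Recording,
    path: str | Path,
    phys_min: float = PHYS_MIN_UV,
    phys_max: float = PHYS_MAX_UV,
) -> None:
    """Write a recording as plain EDF (16-bit, 1-second data records).

    Header date/time fields are fixed constants so identical data produce
    byte-identical files.  Amplitudes must fit the declared physical range;
    the recording length must be a whole number of seconds (EDF data records
    are one second long here).
    """
    path = Path(path)
    n_ch, n_samp = recording.data.shape
    if n_samp == 0:
        raise DataError("refusing to write an empty recording (0 samples)")
    if n_samp % recording.fs != 0:
        raise DataError(
            f"recording length {n_samp} is not a whole number of 1 s records "
            f"at fs={recording.fs}"
        )
    lo, hi = recording.data.min(), recording.data.max()
    if lo < phys_min or hi > phys_max:
        raise DataError(
            f"amplitudes [{lo:.1f}, {hi:.1f}] μV exceed the physical range "
            f"[{phys_min}, {phys_max}] μV"
        )
    n_records = n_samp // recording.fs

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.data - phys_min) / gain).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),                      # patient id (anonymous)
            _pad_ascii(f"Startdate 01-JAN-2000 {recording.id[:40]}", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(256 * (1 + n_ch)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),                              # record duration, s
            _pad_ascii(str(n_ch), 4),
        ]
    )

    def col(values: Iterable[str], width: int) -> bytes:
        return b"".join(_pad_ascii(v, width) for v in values)

    labels = [c[:16] for c in recording.channels]
    header += col(labels, 16)
    header += col([""] * n_ch, 80)                           # transducer
    header += col(["uV"] * n_ch, 8)
    header += col([f"{phys_min:g}"] * n_ch, 8)
    header += col([f"{phys_max:g}"] * n_ch, 8)
    header += col([str(_DIG_MIN)] * n_ch, 8)
    header += col([str(_DIG_MAX)] * n_ch, 8)
    header += col(["BP 0.5-45 Hz"] * n_ch, 80)               # prefiltering note
    header += col([str(recording.fs)] * n_ch, 8)
    header += col([""] * n_ch, 32)

    # EDF interleaves: per data record, all samples of ch1, then ch2, ...
    blocks = digital.reshape(n_ch, n_records, recording.fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# Event CSV
# ---------------------------------------------------------------------------

def _default_parser(path: Path) -> Iterable[tuple[str, float, float]]:
    """Canonical scoring dialect: CSV with header ``label,start_s,end_s``."""
    try:
        df = pd.read_csv(path, dtype={"label": str})
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as scoring CSV: {exc}") from exc
    required = ["label", "start_s", "end_s"]
    if list(df.columns[:3]) != required:
        raise FormatError(
            f"{path}: expected header {','.join(required)}, got {','.join(df.columns)}"
        )
    for row in df.itertuples(index=False):
        yield str(row.label), float(row.start_s), float(row.end_s)


def read_events(
    path: str | Path,
    total_duration_s: float | None = None,
    aliases: dict[str, Label] | None = None,
    parser: Callable[[Path], Iterable[tuple[str, float, float]]] | None = None,
) -> EventList:
    """Read a scoring file into a validated :class:`EventList`.

    ``parser`` may be any callable yielding ``(label_text, start_s, end_s)``
    rows, which lets foreign scoring layouts (e.g. a public dataset's native
    export) plug into the same validation; the default parses the canonical
    CSV dialect.  Label text is matched case-insensitively against the
    vocabulary (W, MSE, MSEc, ED, SLEEP by default).
    """
    path = Path(path)
    rows = (parser or _default_parser)(path)
    events = [
        Event(start_s=s, end_s=e, label=parse_label(lab, aliases))
        for lab, s, e in rows
    ]
    return EventList(events=events, total_duration_s=total_duration_s)


def write_events(events: EventList, path: str | Path) -> None:
    """Write an event list in the canonical CSV dialect (round-trips exactly)."""
    df = pd.DataFrame(
        {
            "label": [e.label.name for e in events],
            "start_s": [repr(float(e.start_s)) for e in events],
            "end_s": [repr(float(e.end_s)) for e in events],
        }
    )
    df.to_csv(path, index=False)
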