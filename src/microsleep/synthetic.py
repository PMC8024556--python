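"""Synthetic EEG/EOG with the spectral structure of wake and microsleep.

The generator emulates the signal phenomenology the detector relies on,
at 40-min maintenance-of-wakefulness-test scale by default:

* **Wake** — occipital alpha (8–12 Hz) rides on broadband background
  noise; the EOG shows occasional blink transients (sharp biphasic
  deflections, same polarity on both channels since both are referenced
  to the left mastoid).
* **MSE** — the EEG slows to theta dominance (4–7 Hz, alpha suppressed);
  every episode is preceded by a slow-eye-movement epoch (0.2–0.6 Hz,
  anti-correlated between the two EOG derivations — horizontal rolling
  movements deflect the eyes' dipoles oppositely), continuing at half
  amplitude into the episode.
* **MSEc / ED** — borderline classes drawn as *overlapping* intermediate
  alpha/theta mixtures: their mixing levels are sampled per event from
  ranges that overlap each other and shade into both wake and MSE.  This
  mirrors their clinical ambiguity and makes them irreducibly hard to
  classify, which is exactly the property the evaluation needs.

Class time-budgets default to the composition of clinical MWT recordings
(~89% wake, 8% MSE, 1% MSEc, 2% ED); microsleep durations are uniform on
1–15 s.  The alpha and theta rhythms are amplitude-modulated sinusoids
whose envelope never vanishes (rhythm presence is the class signature, so
it is switched by the per-class envelopes, not by chance fading);
broadband background, EOG noise and slow eye movements are bandlimited
Gaussian noise.  State boundaries switch exactly at the scored sample.
Everything derives from one integer seed; the same seed reproduces the
recording bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import Event, EventList, Recording
from .labels import Label
from .preprocess import (
    BandpassSpec,
    fourier_bandpass,
    rasterize_events,
    seconds_to_sample,
)

__all__ = [
    "SimConfig",
    "CohortItem",
    "generate_recording",
    "generate_cohort",
    "assign_splits",
    "validate_simulation",
    "SimReport",
]

CHANNELS = ["O1M2", "O2M1", "E1M1", "E2M1"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated maintenance-of-wakefulness test."""

    fs: int = 200
    duration_s: float = 2400.0            # one 40-min MWT
    frac_mse: float = 0.08                # class time fractions (training-set mix)
    frac_msec: float = 0.01
    frac_ed: float = 0.02
    mse_duration_range_s: tuple[float, float] = (1.0, 15.0)
    borderline_duration_range_s: tuple[float, float] = (2.0, 8.0)
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)
    theta_band_hz: tuple[float, float] = (4.0, 7.0)
    sem_band_hz: tuple[float, float] = (0.2, 0.6)
    alpha_uv: float = 20.0                # occipital alpha amplitude (std)
    theta_uv: float = 25.0                # theta amplitude during MSE (std)
    noise_uv: float = 8.0                 # broadband EEG background (std)
    sem_uv: float = 100.0                 # slow-eye-movement EOG deflection (std)
    blink_uv: float = 150.0               # blink peak amplitude
    eog_noise_uv: float = 5.0
    blink_rate_hz: float = 0.2            # mean blink rate while awake
    sem_lead_s: float = 3.0               # slow-eye-movement epoch before each MSE
    min_gap_s: float = 3.0                # minimum wake between events
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_mse + self.frac_msec + self.frac_ed >= 1.0:
            raise ConfigurationError("class fractions must sum to < 1")
        if min(self.frac_mse, self.frac_msec, self.frac_ed) < 0:
            raise ConfigurationError("class fractions must be non-negative")
        lo, hi = self.mse_duration_range_s
        if not 0 < lo < hi:
            raise ConfigurationError("invalid MSE duration range")
        for band in (self.alpha_band_hz, self.theta_band_hz):
            if not 0.5 <= band[0] < band[1] <= 45.0:
                raise ConfigurationError(f"band {band} outside the 0.5–45 Hz passband")
        if self.duration_s < 60:
            raise ConfigurationError("simulated recordings must be ≥ 60 s")


@dataclass
class CohortItem:
    recording: Recording
    events: EventList
    split: str | None = None
    seed: int = 0


def _draw_durations(
    rng: np.random.Generator, target_s: float, lo: float, hi: float
) -> list[float]:
    """Uniform durations accumulating to ≈ target_s (last one trimmed).

    A remainder too small to stand as its own event is folded into the
    previous one (capped at ``hi``) so the realized budget tracks the
    target to within a fraction of one event.
    """
    out: list[float] = []
    total = 0.0
    while total < target_s:
        d = float(rng.uniform(lo, hi))
        if total + d > target_s:
            d = target_s - total
            if d < lo:
                if out:
                    room = hi - out[-1]
                    out[-1] += min(d, room)
                break
        out.append(d)
        total += d
    return out


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> EventList:
    """Lay out non-overlapping events with wake gaps and SEM leads."""
    T = cfg.duration_s
    lo, hi = cfg.mse_duration_range_s
    blo, bhi = cfg.borderline_duration_range_s
    blocks: list[tuple[Label, float, float]] = []  # (label, lead, duration)
    for d in _draw_durations(rng, cfg.frac_mse * T, lo, hi):
        blocks.append((Label.MSE, cfg.sem_lead_s, d))
    for d in _draw_durations(rng, cfg.frac_msec * T, blo, bhi):
        blocks.append((Label.MSEC, 0.0, d))
    for d in _draw_durations(rng, cfg.frac_ed * T, blo, bhi):
        blocks.append((Label.ED, 0.0, d))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    occupied = sum(lead + d for _, lead, d in blocks)
    n_gaps = len(blocks) + 1
    free = T - occupied - cfg.min_gap_s * n_gaps
    if free < 0:
        raise ConfigurationError(
            f"class fractions infeasible: events + gaps need "
            f"{occupied + cfg.min_gap_s * n_gaps:.0f} s > {T:.0f} s"
        )
    gaps = cfg.min_gap_s + free * rng.dirichlet(np.ones(n_gaps))
    events: list[Event] = []
    cursor = 0.0
    for (lab, lead, d), gap in zip(blocks, gaps):
        cursor += gap + lead
        # snap to the sample grid so scored events match the raster exactly
        start = round(cursor * cfg.fs) / cfg.fs
        end = round((cursor + d) * cfg.fs) / cfg.fs
        events.append(Event(start_s=start, end_s=end, label=lab))
        cursor += d
    return EventList(events=events, total_duration_s=T)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: int, band: tuple[float, float]
) -> np.ndarray:
    """Unit-std Gaussian noise restricted to a frequency band."""
    x = fourier_bandpass(rng.standard_normal(n), fs, BandpassSpec(*band))
    sd = x.std()
    return x / sd if sd > 0 else x


def _am_oscillation(
    rng: np.random.Generator, n: int, fs: int, band: tuple[float, float]
) -> np.ndarray:
    """Unit-std rhythmic oscillation: sinusoid with slow amplitude modulation.

    The carrier frequency is drawn once per recording from the interior of
    the band; the envelope waxes and wanes slowly (≤ 1 Hz) but stays within
    [0.5, 1.5], so the rhythm never vanishes the way a band-filtered noise
    realization would.  This is the model for the alpha and theta rhythms:
    cortical rhythms are sustained oscillations, and their *presence or
    absence* is the class signature, so state contrast is carried by the
    per-class envelopes, not by chance fading of the carrier.
    """
    f = rng.uniform(band[0] + 0.5, band[1] - 0.5)
    phi = rng.uniform(0.0, 2 * np.pi)
    slow = fourier_bandpass(rng.standard_normal(n), fs, BandpassSpec(0.5, 1.0))
    sd = slow.std()
    env = np.clip(1.0 + 0.2 * (slow / sd if sd > 0 else slow), 0.5, 1.5)
    x = env * np.sin(2 * np.pi * f * np.arange(n) / fs + phi)
    return x / x.std()


def _blink_pulse(fs: int, dur_s: float) -> np.ndarray:
    """Biphasic blink transient: one positive then one negative lobe."""
    n = int(dur_s * fs)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.sin(2 * np.pi * t) * np.hanning(n)


def generate_recording(
    cfg: SimConfig, rec_id: str = "sim000", seed: int | None = None
) -> tuple[Recording, EventList]:
    """Simulate one labeled recording (4 channels: O1M2, O2M1, E1M1, E2M1)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    events = _place_events(cfg, rng)
    track = rasterize_events(events, n, fs)

    # per-sample envelopes of the two narrowband EEG components
    alpha_env = np.where(track.labels == int(Label.W), 1.0, 0.05)
    theta_env = np.where(track.labels == int(Label.MSE), 1.0, 0.0)
    for ev in events:
        i = seconds_to_sample(ev.start_s, fs)
        j = seconds_to_sample(ev.end_s, fs)
        if ev.label in (Label.MSEC, Label.ED):
            # borderline classes: both bands present at intermediate levels,
            # drawn identically for MSEc and ED so nothing in the signal
            # distinguishes the two from each other
            alpha_env[i:j] = rng.uniform(0.35, 0.75)
            theta_env[i:j] = rng.uniform(0.35, 0.75)

    alpha = _am_oscillation(rng, n, fs, cfg.alpha_band_hz)
    theta = _am_oscillation(rng, n, fs, cfg.theta_band_hz)
    eeg_common = cfg.alpha_uv * alpha_env * alpha + cfg.theta_uv * theta_env * theta
    bb = cfg.noise_uv
    o1m2 = eeg_common + bb * _bandlimited_noise(rng, n, fs, (0.5, 45.0))
    o2m1 = 0.95 * eeg_common + bb * _bandlimited_noise(rng, n, fs, (0.5, 45.0))

    e1m1 = cfg.eog_noise_uv * _bandlimited_noise(rng, n, fs, (0.5, 15.0))
    e2m1 = cfg.eog_noise_uv * _bandlimited_noise(rng, n, fs, (0.5, 15.0))

    # slow eye movements: lead-in before each MSE, half amplitude inside it
    sem = cfg.sem_uv * _bandlimited_noise(rng, n, fs, cfg.sem_band_hz)
    sem_gain = np.zeros(n)
    for ev in events:
        if ev.label is Label.MSE:
            i = seconds_to_sample(ev.start_s, fs)
            j = seconds_to_sample(ev.end_s, fs)
            lead = int(cfg.sem_lead_s * fs)
            sem_gain[max(0, i - lead) : i] = 1.0
            sem_gain[i:j] = 0.5
    e1m1 += sem * sem_gain
    e2m1 -= sem * sem_gain  # horizontal movements: opposite deflections

    # blinks while awake (same polarity on both EOG channels)
    wake = track.labels == int(Label.W)
    pulse = _blink_pulse(fs, 0.3)
    n_blinks = rng.poisson(cfg.blink_rate_hz * wake.sum() / fs)
    wake_idx = np.flatnonzero(wake[: n - len(pulse)])
    if len(wake_idx) and n_blinks:
        for start in rng.choice(wake_idx, size=n_blinks, replace=False):
            seg = slice(start, start + len(pulse))
            if wake[seg].all():
                amp = cfg.blink_uv * rng.uniform(0.7, 1.3)
                e1m1[seg] += amp * pulse
                e2m1[seg] += amp * pulse

    recording = Recording(
        id=rec_id, fs=fs, channels=list(CHANNELS),
        data=np.vstack([o1m2, o2m1, e1m1, e2m1]),
    )
    return recording, events


def assign_splits(n: int, fractions: Sequence[float] = (0.70, 0.15, 0.15)) -> list[str]:
    """Largest-remainder apportionment into train/val/test.

    Ties in the remainders are broken in split order (train, val, test).
    """
    names = ["train", "val", "test"]
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    out: list[str] = []
    for name, c in zip(names, counts):
        out += [name] * c
    return out


def generate_cohort(
    n_recordings: int,
    cfg: SimConfig,
    seed: int | None = None,
    split: bool = False,
) -> list[CohortItem]:
    """Simulate a cohort with deterministic per-recording seeds.

    Per-recording seeds are spawned from the master seed via a seed
    sequence, so the cohort is reproducible as a whole while recordings
    are pairwise independent.  With ``split=True``, recordings are
    assigned to train/val/test in 70/15/15 proportions.
    """
    if n_recordings < 1:
        raise ConfigurationError("need at least one recording")
    master = cfg.seed if seed is None else seed
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master).spawn(n_recordings)
    ]
    splits = assign_splits(n_recordings) if split else [None] * n_recordings
    items = []
    for i, (s, sp) in enumerate(zip(child_seeds, splits)):
        rec, events = generate_recording(cfg, rec_id=f"sim{i:03d}", seed=s)
        items.append(CohortItem(recording=rec, events=events, split=sp, seed=s))
    return items


@dataclass
class SimReport:
    """Self-check of a generated recording against its own configuration."""

    theta_alpha_ratio: dict[str, float]    # per class, power ratio on O1M2
    realized_fractions: dict[str, float]
    durations_in_range: bool
    spectral_ordering_ok: bool
    fractions_ok: bool
    sem_anticorrelation: float | None      # corr(E1M1, E2M1) in SEM epochs
    sem_ok: bool
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = (
            self.durations_in_range
            and self.spectral_ordering_ok
            and self.fractions_ok
            and self.sem_ok
        )


def validate_simulation(
    recording: Recording, events: EventList, cfg: SimConfig
) -> SimReport:
    """Verify band-power ordering, class budgets, durations and EOG structure."""
    fs = recording.fs
    n = recording.n_samples
    track = rasterize_events(events, n, fs)

    eeg = recording.channel("O1M2")
    theta = fourier_bandpass(eeg, fs, BandpassSpec(*cfg.theta_band_hz))
    alpha = fourier_bandpass(eeg, fs, BandpassSpec(*cfg.alpha_band_hz))
    ratios: dict[str, float] = {}
    fracs: dict[str, float] = {}
    for cls in (Label.W, Label.MSE, Label.MSEC, Label.ED):
        mask = track.labels == int(cls)
        fracs[cls.name] = float(mask.mean())
        if mask.any():
            ratios[cls.name] = float((theta[mask] ** 2).mean() / (alpha[mask] ** 2).mean())

    spectral_ok = True
    if "MSE" in ratios and "W" in ratios:
        spectral_ok = ratios["MSE"] > ratios["W"]

    # the ±20% relative budget tolerance is only meaningful from ~10 min up;
    # shorter recordings cannot realize a 1% class at all
    targets = {"MSE": cfg.frac_mse, "MSEC": cfg.frac_msec, "ED": cfg.frac_ed}
    if cfg.duration_s >= 600:
        fractions_ok = all(
            abs(fracs[k] - t) <= 0.2 * t if t > 0 else fracs[k] == 0.0
            for k, t in targets.items()
        )
    else:
        fractions_ok = all(fracs[k] == 0.0 for k, t in targets.items() if t == 0)

    lo, hi = cfg.mse_duration_range_s
    durations_ok = all(
        lo - 1e-9 <= ev.duration_s <= hi + 1e-9
        for ev in events
        if ev.label is Label.MSE
    )

    # SEM epochs are the sem_lead_s windows preceding each MSE onset
    sem_corr: float | None = None
    segs = []
    for ev in events:
        if ev.label is Label.MSE:
            i = seconds_to_sample(ev.start_s, fs)
            segs.append(slice(max(0, i - int(cfg.sem_lead_s * fs)), i))
    if segs:
        e1 = np.concatenate([recording.channel("E1M1")[s] for s in segs])
        e2 = np.concatenate([recording.channel("E2M1")[s] for s in segs])
        sem_corr = float(np.corrcoef(e1, e2)[0, 1])
    sem_ok = sem_corr is None or sem_corr < -0.5

    return SimReport(
        theta_alpha_ratio=ratios,
        realized_fractions=fracs,
        durations_in_range=durations_ok,
        spectral_ordering_ok=spectral_ok,
        fractions_ok=fractions_ok,
        sem_anticorrelation=sem_corr,
        sem_ok=sem_ok,
    )
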