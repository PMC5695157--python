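"""Deterministic EEG conditioning: re-referencing, filtering, epoching.

All operations are pure functions of their inputs — running the chain twice
on the same recording is bit-identical.  The band-pass is a 4th-order
Butterworth applied forward-backward (zero phase), standard practice for
evoked-response work where phase distortion would corrupt spatiotemporal
templates.  Downsampling is strict integer decimation (anti-alias FIR +
pick every q-th sample); event indices are rescaled by integer division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import SegmentStack

__all__ = [
    "RawRecording",
    "EpochConfig",
    "rereference",
    "regress_eog",
    "bandpass",
    "cut_epochs",
    "baseline",
    "downsample",
    "condition_trials",
    "downsample_recording",
]


@dataclass
class RawRecording:
    """Continuous multichannel recording with an event table.

    ``events`` is an integer array of shape (k, 2) holding
    (sample_index, event_code) rows, sample indices at the recording's own
    sampling rate (0-based).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 2)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        if self.events.size and (self.events[:, 0].min() < 0
                                 or self.events[:, 0].max() >= self.data.shape[1]):
            raise ValueError("event sample indices outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochConfig:
    """Epoch window relative to an event, in seconds."""

    t_start: float
    t_end: float
    baseline_window: tuple[float, float] | None = None
    target_fs: float | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.baseline_window is not None and self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede or touch the event onset")


def rereference(rec: RawRecording, ref_channels: list[str]) -> RawRecording:
    """Subtract the mean of the reference channels from every channel."""
    missing = [c for c in ref_channels if c not in rec.channel_names]
    if missing:
        raise ValueError(f"reference channel(s) not in recording: {missing}")
    idx = [rec.channel_names.index(c) for c in ref_channels]
    ref = rec.data[idx].mean(axis=0)
    return RawRecording(data=rec.data - ref, fs=rec.fs,
                        channel_names=list(rec.channel_names), events=rec.events.copy())


def regress_eog(rec: RawRecording, eog_channels: list[str]) -> RawRecording:
    """Optional ocular-artifact hook: least-squares EOG regression.

    Subtracts from every non-EOG channel its least-squares projection onto
    the EOG channels.  Off by default in all pipelines (the hook exists for
    recordings that include ocular electrodes).
    """
    missing = [c for c in eog_channels if c not in rec.channel_names]
    if missing:
        raise ValueError(f"EOG channel(s) not in recording: {missing}")
    idx = [rec.channel_names.index(c) for c in eog_channels]
    eog = rec.data[idx]
    data = rec.data.copy()
    rest = [i for i in range(data.shape[0]) if i not in idx]
    beta, *_ = np.linalg.lstsq(eog.T, data[rest].T, rcond=None)
    data[rest] -= beta.T @ eog
    return RawRecording(data=data, fs=rec.fs,
                        channel_names=list(rec.channel_names), events=rec.events.copy())


def bandpass(rec: RawRecording | np.ndarray, lo: float, hi: float,
             fs: float | None = None, order: int = 4):
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz.

    Accepts a :class:`RawRecording` (returns the same) or a bare
    (channels, samples) array with ``fs`` given.
    """
    if isinstance(rec, RawRecording):
        out = bandpass(rec.data, lo, hi, fs=rec.fs, order=order)
        return RawRecording(data=out, fs=rec.fs,
                            channel_names=list(rec.channel_names), events=rec.events.copy())
    if fs is None:
        raise ValueError("fs required for array input")
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) Hz for fs={fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(rec, dtype=float), axis=-1)


def cut_epochs(rec: RawRecording, cfg: EpochConfig,
               event_codes: list[int] | None = None,
               strict: bool = True) -> tuple[SegmentStack, np.ndarray]:
    """Cut fixed-length epochs time-locked to events.

    Epoch k spans samples ``floor(idx + t_start*fs)`` (inclusive) to
    ``floor(idx + t_end*fs)`` (exclusive) — a half-open window with floor
    rounding, so 0.6 s at 64 Hz yields 38 samples.  Returns the stack and
    the event code of each kept epoch.  Out-of-bounds windows raise in
    strict mode and are skipped (with a count attached as ``n_skipped``)
    otherwise.
    """
    fs = rec.fs
    events = rec.events
    if event_codes is not None:
        events = events[np.isin(events[:, 1], event_codes)]
    if events.shape[0] == 0:
        raise ValueError("no matching events")
    starts = np.floor(events[:, 0] + cfg.t_start * fs).astype(int)
    stops = np.floor(events[:, 0] + cfg.t_end * fs).astype(int)
    lengths = stops - starts
    if lengths.min() != lengths.max():  # can only occur with non-integer event grids
        raise ValueError("inconsistent epoch lengths across events")
    ok = (starts >= 0) & (stops <= rec.n_samples)
    n_skipped = int((~ok).sum())
    if n_skipped and strict:
        raise ValueError(f"{n_skipped} epoch window(s) out of bounds")
    starts, stops = starts[ok], stops[ok]
    codes = events[ok, 1]
    n = int(lengths[0])
    data = np.empty((rec.data.shape[0], n, len(starts)))
    for k, s in enumerate(starts):
        data[:, :, k] = rec.data[:, s:s + n]
    stack = SegmentStack(data=data, fs=fs, channel_names=list(rec.channel_names))
    stack.n_skipped = n_skipped  # type: ignore[attr-defined]
    return stack, codes


def baseline(stack: SegmentStack, window: float) -> SegmentStack:
    """Subtract the mean of the first ``floor(window*fs)`` samples.

    Epochs must have been cut to include that pre-onset span at the start
    of the window; the mean is removed per channel, per epoch.
    """
    nb = int(np.floor(window * stack.fs))
    if nb <= 0:
        raise ValueError("baseline window shorter than one sample")
    if nb > stack.n:
        raise ValueError("baseline window exceeds epoch length")
    means = stack.data[:, :nb, :].mean(axis=1, keepdims=True)
    return SegmentStack(data=stack.data - means, fs=stack.fs,
                        channel_names=stack.channel_names)


def _decimation_stages(q: int) -> list[int]:
    """Split a decimation factor into stages <= 10 (FIR stability/quality)."""
    stages: list[int] = []
    while q > 10:
        for f in (10, 8, 7, 6, 5, 4, 3, 2):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:  # prime > 10; decimate in one (rare) stage
            break
    if q > 1:
        stages.append(q)
    return stages


def downsample(data: np.ndarray | SegmentStack, fs: float, target_fs: float):
    """Anti-alias filter and decimate to ``target_fs``.

    ``fs / target_fs`` must be an integer; the output length is
    ``floor(n * target_fs / fs)``.  Works on (channels, samples) arrays and
    on :class:`SegmentStack` (per-segment, along the sample axis).
    """
    ratio = fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError("resampling ratio must be integer")
    if isinstance(data, SegmentStack):
        out = downsample(np.moveaxis(data.data, 1, -1), fs, target_fs)
        return SegmentStack(data=np.moveaxis(out, -1, 1), fs=target_fs,
                            channel_names=data.channel_names)
    x = np.asarray(data, dtype=float)
    n_out = x.shape[-1] // q
    if q == 1:
        return x.copy()
    for f in _decimation_stages(q):
        x = signal.decimate(x, f, ftype="fir", zero_phase=True, axis=-1)
    return x[..., :n_out]


def condition_trials(ts, band: tuple[float, float] | None = None,
                     target_fs: float | None = None):
    """Band-pass and decimate a raw :class:`~stbf.containers.TrialSet`.

    Defaults come from the paradigm preset (``ts.paradigm``); per-trial
    event indices are rescaled by the decimation factor.
    """
    from .config import PREPROCESS_PRESETS
    from .containers import TrialSet

    preset = PREPROCESS_PRESETS.get(ts.paradigm, {})
    band = band if band is not None else preset.get("band")
    target_fs = target_fs if target_fs is not None else preset.get("target_fs", ts.fs)
    data = np.moveaxis(ts.data, 1, -1)  # (m, r, n): filter along samples
    if band is not None:
        data = bandpass(data, band[0], band[1], fs=ts.fs)
    q = int(round(ts.fs / target_fs))
    data = downsample(data, ts.fs, target_fs)
    events = ts.events
    if events is not None and q > 1:
        events = [np.column_stack([e[:, 0] // q, e[:, 1]]) for e in events]
    return TrialSet(data=np.moveaxis(data, -1, 1), fs=target_fs, cues=ts.cues.copy(),
                    channel_names=list(ts.channel_names), events=events,
                    paradigm=ts.paradigm)


def downsample_recording(rec: RawRecording, target_fs: float) -> RawRecording:
    """Downsample a recording; event indices are divided by the factor."""
    q = int(round(rec.fs / target_fs))
    data = downsample(rec.data, rec.fs, target_fs)
    events = rec.events.copy()
    if events.size:
        events[:, 0] = events[:, 0] // q
    return RawRecording(data=data, fs=target_fs,
                        channel_names=list(rec.channel_names), events=events)
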