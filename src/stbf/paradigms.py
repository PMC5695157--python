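"""Paradigm-specific template construction and feature extraction.

Three synchronous visual BCI paradigms are supported, each reducing a trial
to a vector of beamformer outputs, one per selectable target:

* **P300** — targets are highlighted serially; a single spatiotemporal
  template (target-minus-non-target average epoch) and a single beamformer
  are built.  Per trial, epochs are averaged per highlighted target and the
  beamformer output of each average is that target's score.
* **SSVEP** — targets flicker at fixed frequency/phase combinations; per
  target, trials are cut into non-overlapping segments one stimulus period
  long, the cued-trial segment average is the template, and one beamformer
  per target is built against a covariance pooled over all training trials
  segmented at that target's period.
* **cVEP** — targets show lagged copies of one m-sequence; trials are cut
  into one-sequence-long segments, per-target templates are cued-segment
  averages, and a single pooled covariance serves all targets.

Scores are calibrated by the LCMV constraint: a trial whose averaged
segment equals target i's template scores exactly y_i = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TrialSet
from .core import (
    BeamformerWeights,
    PooledCovariance,
    SegmentStack,
    SpatiotemporalPattern,
    estimate_covariance,
    flatten_segments,
    lcmv_weights,
    apply_beamformer,
)
from .msequence import MSequence, generate_msequence

__all__ = [
    "ParadigmSpec",
    "p300_spec",
    "ssvep_spec",
    "cvep_spec",
    "get_spec",
    "p300_epochs",
    "p300_pattern",
    "p300_features",
    "ssvep_segments",
    "ssvep_patterns_and_weights",
    "ssvep_features",
    "cvep_segment_length",
    "cvep_segments",
    "cvep_patterns_and_weights",
    "cvep_features",
    "FittedBeamformers",
    "fit_paradigm",
    "trialset_features",
]


@dataclass
class ParadigmSpec:
    """Stimulation-protocol description for one paradigm.

    Only the fields relevant to ``kind`` are used.  Defaults reproduce the
    three study protocols: a 9-target serial-highlight speller (100 ms
    highlight, 100 ms ISI, 15 highlights per target, 4 cues per target), a
    4-target 12/15 Hz, 0/pi flicker matrix (5-s trials, 15 cues per
    target), and a 32-target 63-bit m-sequence interface at 120 Hz frame
    rate (10 repetitions, 5 cues per target).
    """

    kind: str
    n_targets: int
    cues_per_target: int
    # serial-highlight (P300) parameters
    soa: float = 0.2
    highlight_duration: float = 0.1
    highlights_per_target: int = 15
    epoch_seconds: float = 0.6
    baseline_seconds: float = 0.1
    # flicker (SSVEP) parameters
    frequencies: tuple[float, ...] = ()
    phases: tuple[float, ...] = ()
    transient_skip: float = 0.12
    trial_seconds: float = 5.0
    # code (cVEP) parameters
    msequence: MSequence | None = None
    frame_rate: float = 120.0
    lags: tuple[int, ...] = ()
    repetitions: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("p300", "ssvep", "cvep"):
            raise ValueError(f"unknown paradigm kind {self.kind!r}")
        if self.n_targets < 2:
            raise ValueError("need at least 2 targets")
        if self.kind == "ssvep":
            if len(self.frequencies) != self.n_targets or len(self.phases) != self.n_targets:
                raise ValueError("one (frequency, phase) pair per target required")
            if min(self.frequencies) <= 0:
                raise ValueError("frequencies must be positive")
        if self.kind == "cvep":
            if self.msequence is None:
                raise ValueError("cvep spec requires an m-sequence")
            if len(self.lags) != self.n_targets:
                raise ValueError("one lag per target required")
            if len(set(self.lags)) != self.n_targets or max(self.lags) >= len(self.msequence):
                raise ValueError("lags must be distinct and shorter than the sequence")

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.cues_per_target


def p300_spec(**overrides) -> ParadigmSpec:
    """9-target serial-highlight preset (36 trials)."""
    kw = dict(kind="p300", n_targets=9, cues_per_target=4)
    kw.update(overrides)
    return ParadigmSpec(**kw)


def ssvep_spec(**overrides) -> ParadigmSpec:
    """4-target 12/15 Hz, 0/pi phase flicker preset (60 five-second trials)."""
    kw = dict(
        kind="ssvep", n_targets=4, cues_per_target=15,
        frequencies=(12.0, 12.0, 15.0, 15.0),
        phases=(0.0, np.pi, 0.0, np.pi),
    )
    kw.update(overrides)
    return ParadigmSpec(**kw)


def cvep_spec(**overrides) -> ParadigmSpec:
    """32-target lagged 63-bit m-sequence preset (160 trials).

    Default taps x^6 + x^5 + 1; target lags evenly spaced at
    floor(63 * i / 32) frames.
    """
    kw = dict(
        kind="cvep", n_targets=32, cues_per_target=5,
        msequence=generate_msequence(6, (6, 5)),
        lags=tuple(int(np.floor(63 * i / 32)) for i in range(32)),
    )
    kw.update(overrides)
    return ParadigmSpec(**kw)


_SPEC_FACTORIES = {"p300": p300_spec, "ssvep": ssvep_spec, "cvep": cvep_spec}


def get_spec(kind: str, **overrides) -> ParadigmSpec:
    """Preset :class:`ParadigmSpec` by paradigm name."""
    try:
        return _SPEC_FACTORIES[kind](**overrides)
    except KeyError:
        raise ValueError(f"unknown paradigm kind {kind!r}") from None


# ---------------------------------------------------------------------------
# P300


def _select_repetitions(events: np.ndarray, n_targets: int,
                        reps: int | None) -> np.ndarray:
    """Keep the first ``reps`` highlights of each target (temporal order)."""
    if reps is None:
        return events
    keep = []
    seen = np.zeros(n_targets, dtype=int)
    for row in events:
        t = row[1]
        if seen[t] < reps:
            keep.append(row)
            seen[t] += 1
    return np.array(keep, dtype=int).reshape(-1, 2)


def p300_epochs(ts: TrialSet, spec: ParadigmSpec, reps: int | None = None
                ) -> tuple[SegmentStack, np.ndarray, np.ndarray]:
    """Cut baselined post-highlight epochs from every trial.

    Epochs span [0, epoch_seconds) after each highlight onset,
    baseline-corrected with the mean of the ``baseline_seconds`` pre-onset
    span.  With ``reps`` given, only the first ``reps`` highlights per
    target of each trial are used.

    Returns
    -------
    epochs : SegmentStack
    trial_index : ndarray
        Trial of origin for every epoch.
    highlighted : ndarray
        Highlighted target index for every epoch.
    """
    if ts.events is None:
        raise ValueError("serial-highlight trials require per-trial event tables")
    fs = ts.fs
    n_post = int(np.floor(spec.epoch_seconds * fs))
    n_pre = int(np.floor(spec.baseline_seconds * fs))
    if n_pre <= 0:
        raise ValueError("baseline window shorter than one sample")
    chunks, trial_idx, highlighted = [], [], []
    for k in range(ts.n_trials):
        ev = _select_repetitions(ts.events[k], spec.n_targets, reps)
        for onset, target in ev:
            if onset - n_pre < 0 or onset + n_post > ts.n_samples:
                raise ValueError("epoch window out of trial bounds")
            ep = ts.data[:, onset - n_pre:onset + n_post, k]
            ep = ep - ep[:, :n_pre].mean(axis=1, keepdims=True)
            chunks.append(ep[:, n_pre:])
            trial_idx.append(k)
            highlighted.append(target)
    stack = SegmentStack(data=np.stack(chunks, axis=-1), fs=fs,
                         channel_names=list(ts.channel_names))
    return stack, np.array(trial_idx, dtype=int), np.array(highlighted, dtype=int)


def p300_pattern(epochs: SegmentStack, is_target: np.ndarray) -> SpatiotemporalPattern:
    """Target-minus-non-target average epoch, A = mean(S_t) - mean(S_nt)."""
    is_target = np.asarray(is_target, dtype=bool)
    if is_target.shape != (epochs.r,):
        raise ValueError("is_target must have one flag per epoch")
    if not is_target.any() or is_target.all():
        raise ValueError("need at least one target and one non-target epoch")
    a = epochs.data[:, :, is_target].mean(axis=2) - epochs.data[:, :, ~is_target].mean(axis=2)
    return SpatiotemporalPattern(pattern=a, label="p300")


def p300_features(trial_epochs: SegmentStack, target_of_epoch: np.ndarray,
                  weights: BeamformerWeights, n_targets: int) -> np.ndarray:
    """Per-target scores for one trial: average epochs per highlighted
    target, then apply the single beamformer to each average."""
    target_of_epoch = np.asarray(target_of_epoch, dtype=int)
    y = np.empty(n_targets)
    for i in range(n_targets):
        sel = target_of_epoch == i
        if not sel.any():
            raise ValueError(f"target {i} has no epochs in this trial")
        y[i] = apply_beamformer(weights, trial_epochs.data[:, :, sel].mean(axis=2))
    return y


# ---------------------------------------------------------------------------
# SSVEP


def ssvep_segments(trial: np.ndarray, f: float, fs: float,
                   skip: float = 0.0,
                   channel_names: list[str] | None = None) -> SegmentStack:
    """Cut one trial into non-overlapping single-period segments of frequency f.

    Segment s is the floor(fs / f) samples starting at sample
    floor(skip * fs + s * fs / f), i.e. each segment is aligned to the
    true stimulus-period boundary and the fractional remainder of the
    period is dropped per segment rather than accumulated; only complete
    segments are kept.  The initial ``skip`` seconds (unstable response)
    are discarded.
    """
    trial = np.asarray(trial, dtype=float)
    n = int(np.floor(fs / f))
    period = fs / f
    start0 = skip * fs
    count = int(np.floor((trial.shape[1] - n - np.floor(start0)) / period)) + 1
    if count < 1:
        raise ValueError("trial too short for a single-period segment")
    starts = np.floor(start0 + np.arange(count) * period).astype(int)
    starts = starts[starts + n <= trial.shape[1]]
    if starts.size < 1:
        raise ValueError("trial too short for a single-period segment")
    segs = trial[:, starts[:, None] + np.arange(n)]  # (m, count, n)
    return SegmentStack(data=np.transpose(segs, (0, 2, 1)).copy(), fs=fs,
                        channel_names=channel_names)


def _truncate(ts: TrialSet, n_keep: int | None) -> np.ndarray:
    if n_keep is None or n_keep >= ts.n_samples:
        return ts.data
    return ts.data[:, :n_keep, :]


def ssvep_patterns_and_weights(
    ts: TrialSet, spec: ParadigmSpec, ridge: float = 0.0,
    seconds: float | None = None, pool_all_trials: bool = True,
) -> list[tuple[SpatiotemporalPattern, BeamformerWeights]]:
    """One (template, beamformer) pair per flicker target.

    Target i's template is the average of single-period segments from the
    trials during which i was cued; its covariance is pooled over segments
    of all training trials cut at i's period (set ``pool_all_trials=False``
    to restrict pooling to cued trials).  ``seconds`` truncates every trial
    before segmentation.
    """
    n_keep = None if seconds is None else int(np.floor(seconds * ts.fs))
    data = _truncate(ts, n_keep)
    out = []
    for i in range(spec.n_targets):
        f = spec.frequencies[i]
        cued = np.flatnonzero(ts.cues == i)
        if cued.size == 0:
            raise ValueError(f"target {i} never cued in training data")
        all_segs, cued_segs = [], []
        for k in range(ts.n_trials):
            st = ssvep_segments(data[:, :, k], f, ts.fs, skip=spec.transient_skip)
            if pool_all_trials or k in cued:
                all_segs.append(st.data)
            if k in cued:
                cued_segs.append(st.data)
        pooled = SegmentStack(data=np.concatenate(all_segs, axis=2), fs=ts.fs)
        pattern = SpatiotemporalPattern(
            pattern=np.concatenate(cued_segs, axis=2).mean(axis=2), label=i)
        cov = estimate_covariance(flatten_segments(pooled), ridge=ridge)
        out.append((pattern, lcmv_weights(cov, pattern)))
    return out


def ssvep_features(trial: np.ndarray, fs: float, spec: ParadigmSpec,
                   weights: list[BeamformerWeights],
                   seconds: float | None = None) -> np.ndarray:
    """Per-target scores: segment the trial at each target's period,
    average the segments, apply that target's beamformer."""
    trial = np.asarray(trial, dtype=float)
    if seconds is not None:
        trial = trial[:, :int(np.floor(seconds * fs))]
    y = np.empty(spec.n_targets)
    for i in range(spec.n_targets):
        st = ssvep_segments(trial, spec.frequencies[i], fs, skip=spec.transient_skip)
        y[i] = apply_beamformer(weights[i], st.data.mean(axis=2))
    return y


# ---------------------------------------------------------------------------
# cVEP


def cvep_segment_length(spec: ParadigmSpec, fs: float) -> int:
    """Samples per full code cycle: round(fs * seq_len / frame_rate)."""
    return int(round(fs * len(spec.msequence) / spec.frame_rate))


def cvep_segments(trial: np.ndarray, fs: float, spec: ParadigmSpec,
                  channel_names: list[str] | None = None) -> SegmentStack:
    """Cut a trial into the maximal number of one-code-cycle segments."""
    trial = np.asarray(trial, dtype=float)
    n = cvep_segment_length(spec, fs)
    count = trial.shape[1] // n
    if count < 1:
        raise ValueError("trial shorter than one code cycle")
    segs = trial[:, :count * n].reshape(trial.shape[0], count, n)
    return SegmentStack(data=np.transpose(segs, (0, 2, 1)).copy(), fs=fs,
                        channel_names=channel_names)


def cvep_patterns_and_weights(
    ts: TrialSet, spec: ParadigmSpec, ridge: float = 0.0,
    repetitions: int | None = None,
) -> list[tuple[SpatiotemporalPattern, BeamformerWeights]]:
    """One (template, beamformer) pair per code target.

    Templates are estimated independently per target by averaging the
    cued-trial segments; a single covariance pooled over segments of all
    training trials (all targets) serves every beamformer.
    """
    n_seg = cvep_segment_length(spec, ts.fs)
    n_keep = None if repetitions is None else repetitions * n_seg
    data = _truncate(ts, n_keep)
    stacks = [cvep_segments(data[:, :, k], ts.fs, spec) for k in range(ts.n_trials)]
    pooled = SegmentStack(data=np.concatenate([s.data for s in stacks], axis=2), fs=ts.fs)
    cov = estimate_covariance(flatten_segments(pooled), ridge=ridge)
    out = []
    for i in range(spec.n_targets):
        cued = np.flatnonzero(ts.cues == i)
        if cued.size == 0:
            raise ValueError(f"target {i} never cued in training data")
        segs = np.concatenate([stacks[k].data for k in cued], axis=2)
        pattern = SpatiotemporalPattern(pattern=segs.mean(axis=2), label=i)
        out.append((pattern, lcmv_weights(cov, pattern)))
    return out


def cvep_features(trial: np.ndarray, fs: float, spec: ParadigmSpec,
                  weights: list[BeamformerWeights],
                  repetitions: int | None = None) -> np.ndarray:
    """Per-target scores: average all code-cycle segments of the trial
    once, then apply every target's beamformer to that single average."""
    trial = np.asarray(trial, dtype=float)
    if repetitions is not None:
        trial = trial[:, :repetitions * cvep_segment_length(spec, fs)]
    avg = cvep_segments(trial, fs, spec).data.mean(axis=2)
    return np.array([apply_beamformer(w, avg) for w in weights])


# ---------------------------------------------------------------------------
# Unified fit/transform used by the decoder model and cross-validation


@dataclass
class FittedBeamformers:
    """Patterns and weights fitted on one training set."""

    spec: ParadigmSpec
    patterns: list[SpatiotemporalPattern]
    weights: list[BeamformerWeights]
    covariance_dims: list[int]
    length: object = None  # repetitions (p300/cvep) or seconds (ssvep)


def fit_paradigm(ts: TrialSet, spec: ParadigmSpec, ridge: float = 0.0,
                 length: float | int | None = None) -> FittedBeamformers:
    """Fit patterns, pooled covariance(s) and beamformer(s) on ``ts``.

    ``length`` truncates the training trials to the evaluated stimulation
    length: highlight repetitions for P300, seconds for SSVEP, code
    repetitions for cVEP.  ``None`` uses the full trials.
    """
    if spec.kind == "p300":
        reps = None if length is None else int(length)
        epochs, trial_idx, highlighted = p300_epochs(ts, spec, reps=reps)
        is_target = highlighted == ts.cues[trial_idx]
        pattern = p300_pattern(epochs, is_target)
        cov = estimate_covariance(flatten_segments(epochs), ridge=ridge)
        w = lcmv_weights(cov, pattern)
        return FittedBeamformers(spec=spec, patterns=[pattern], weights=[w],
                                 covariance_dims=[cov.dim], length=reps)
    if spec.kind == "ssvep":
        pairs = ssvep_patterns_and_weights(ts, spec, ridge=ridge, seconds=length)
        return FittedBeamformers(
            spec=spec,
            patterns=[p for p, _ in pairs],
            weights=[w for _, w in pairs],
            covariance_dims=[w.m * w.n for _, w in pairs],
            length=length,
        )
    reps = None if length is None else int(length)
    pairs = cvep_patterns_and_weights(ts, spec, ridge=ridge, repetitions=reps)
    return FittedBeamformers(
        spec=spec,
        patterns=[p for p, _ in pairs],
        weights=[w for _, w in pairs],
        covariance_dims=[w.m * w.n for _, w in pairs],
        length=reps,
    )


def trialset_features(ts: TrialSet, fitted: FittedBeamformers,
                      length: float | int | None = None) -> np.ndarray:
    """Feature matrix (n_trials, n_targets) of beamformer outputs."""
    spec = fitted.spec
    rows = []
    if spec.kind == "p300":
        reps = None if length is None else int(length)
        for k in range(ts.n_trials):
            sub = ts.subset([k])
            epochs, _, highlighted = p300_epochs(sub, spec, reps=reps)
            rows.append(p300_features(epochs, highlighted, fitted.weights[0],
                                      spec.n_targets))
    elif spec.kind == "ssvep":
        for k in range(ts.n_trials):
            rows.append(ssvep_features(ts.data[:, :, k], ts.fs, spec,
                                       fitted.weights, seconds=length))
    else:
        reps = None if length is None else int(length)
        for k in range(ts.n_trials):
            rows.append(cvep_features(ts.data[:, :, k], ts.fs, spec,
                                      fitted.weights, repetitions=reps))
    return np.vstack(rows)
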