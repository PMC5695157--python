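"""Synthetic multichannel EEG sessions with ground truth.

Each preset emulates one study protocol end-to-end: a 9-target serial
highlighter (15 highlights per target at 200 ms SOA, an evoked template on
cued-target highlights, 36 trials), a 4-target 12/15 Hz 0/pi flicker matrix
(5-s trials, 60 trials), and a 32-target lagged 63-bit m-sequence interface
at 120 Hz frame rate (10 code repetitions, 160 trials).  Responses are
embedded in colored (1/f) or white noise at a configurable SNR, defined as
the RMS of the clean response on its active channels divided by the noise
RMS on those channels over the whole trial.

The generator emulates the statistical structure the decoder relies on —
timing, codes, phase-locked templates, colored background — not head-model
physics; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DEFAULT_MONTAGE, TrialSet
from .config import PREPROCESS_PRESETS, SYNTH_FS
from .msequence import MSequence, generate_msequence
from .paradigms import ParadigmSpec, fit_paradigm, get_spec, trialset_features
from .preprocess import condition_trials

__all__ = ["SynthConfig", "generate_session", "generate_msequence",
           "simulate_accuracy", "snr_sweep"]

# Relative scalp weights of the clean responses on the default montage.
# The decoder never sees these maps; they are a modeling choice.
_P3_MAP = {"Fz": 0.3, "Cz": 0.8, "Pz": 1.0, "Oz": 0.25, "O1": 0.15,
           "O2": 0.15, "PO3": 0.4, "PO4": 0.4, "P3": 0.6, "P4": 0.6}
_N2_MAP = {"Oz": 1.0, "O1": 0.7, "O2": 0.7, "PO3": 0.4, "PO4": 0.4}
_SSVEP_MAP = {"Oz": 1.0, "O1": 0.8, "O2": 0.8, "PO3": 0.5, "PO4": 0.5, "Pz": 0.2}
_CVEP_MAP = {"Oz": 1.0, "O1": 0.8, "O2": 0.8, "PO3": 0.6, "PO4": 0.6, "Pz": 0.3}


@dataclass
class SynthConfig:
    """Generator settings; the seed fixes every source of randomness."""

    spec: ParadigmSpec
    fs: float | None = None
    snr: float = 0.25
    noise: str = "pink"
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs is None:
            self.fs = SYNTH_FS[self.spec.kind]
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")
        if self.noise not in ("pink", "white"):
            raise ValueError("noise must be 'pink' or 'white'")
        if self.spec.kind == "cvep":
            spf = self.fs / self.spec.frame_rate
            if abs(spf - round(spf)) > 1e-9:
                raise ValueError("fs must be an integer multiple of the frame rate")


def _map_to_vector(weight_map: dict, channel_names: list[str]) -> np.ndarray:
    return np.array([weight_map.get(c, 0.0) for c in channel_names])


def _pink_noise(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    """1/f-amplitude noise, unit RMS per channel, zero DC."""
    white = rng.standard_normal((m, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * amp, n=n, axis=1)
    return x / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))


def _white_noise(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    x = rng.standard_normal((m, n))
    return x / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))


def _p300_template(fs: float, channel_names: list[str],
                   duration: float = 0.6) -> np.ndarray:
    """Canonical evoked template: centro-parietal positivity peaking at
    300 ms (~200 ms wide) plus a smaller occipital negativity at 200 ms."""
    t = np.arange(int(round(duration * fs))) / fs
    p3 = np.exp(-0.5 * ((t - 0.30) / 0.08) ** 2)
    n2 = -np.exp(-0.5 * ((t - 0.20) / 0.03) ** 2)
    return (np.outer(_map_to_vector(_P3_MAP, channel_names), p3)
            + 0.5 * np.outer(_map_to_vector(_N2_MAP, channel_names), n2))


def _cvep_period_response(spec: ParadigmSpec, fs: float, lag: int) -> np.ndarray:
    """One period of the code response: the lagged m-sequence, frame-expanded
    and circularly convolved with a short biphasic evoked kernel."""
    spf = int(round(fs / spec.frame_rate))
    code = np.repeat(np.roll(spec.msequence.signed, lag), spf).astype(float)
    n = code.size
    t = np.arange(int(round(0.25 * fs))) / fs
    kernel = (np.exp(-0.5 * ((t - 0.06) / 0.015) ** 2)
              - 0.8 * np.exp(-0.5 * ((t - 0.11) / 0.025) ** 2))
    kern = np.zeros(n)
    kern[:kernel.size] = kernel
    return np.fft.irfft(np.fft.rfft(code) * np.fft.rfft(kern), n=n)


def _clean_trial(spec: ParadigmSpec, cfg: SynthConfig, cue: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Noise-free (m, n) trial for one cue, plus the event table (P300)."""
    fs = cfg.fs
    m = len(cfg.channel_names)
    if spec.kind == "p300":
        pad_pre, pad_post = 0.3, 0.8
        n = int(round((pad_pre + spec.highlights_per_target * spec.n_targets
                       * spec.soa + pad_post) * fs))
        data = np.zeros((m, n))
        template = _p300_template(fs, cfg.channel_names, spec.epoch_seconds)
        order = np.concatenate([rng.permutation(spec.n_targets)
                                for _ in range(spec.highlights_per_target)])
        onsets = np.floor((pad_pre + np.arange(order.size) * spec.soa) * fs).astype(int)
        for onset, target in zip(onsets, order):
            if target == cue:
                data[:, onset:onset + template.shape[1]] += template
        events = np.column_stack([onsets, order])
        return data, events
    if spec.kind == "ssvep":
        n = int(round(spec.trial_seconds * fs))
        t = np.arange(n) / fs
        ramp = np.clip(t / 0.15, 0.0, 1.0)  # unstable initial response
        wave = ramp * np.sin(2 * np.pi * spec.frequencies[cue] * t + spec.phases[cue])
        return np.outer(_map_to_vector(_SSVEP_MAP, cfg.channel_names), wave), None
    # cvep
    period = _cvep_period_response(spec, fs, spec.lags[cue])
    wave = np.tile(period, spec.repetitions)
    return np.outer(_map_to_vector(_CVEP_MAP, cfg.channel_names), wave), None


def generate_session(cfg: SynthConfig) -> TrialSet:
    """Generate one labeled session as a raw :class:`TrialSet`.

    Trials are returned at the generator rate ``cfg.fs`` (unfiltered);
    :func:`stbf.preprocess.condition_trials` brings them to the analysis
    rate.  Cue order cycles through all targets ``cues_per_target`` times.
    Identical configs (including seed) give bit-identical output.
    """
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    cues = np.tile(np.arange(spec.n_targets), spec.cues_per_target)
    noise_fn = _pink_noise if cfg.noise == "pink" else _white_noise
    trials, events = [], []
    for cue in cues:
        clean, ev = _clean_trial(spec, cfg, int(cue), rng)
        active = np.abs(clean).sum(axis=1) > 0
        data = clean.copy()
        if np.isfinite(cfg.snr):
            noise = noise_fn(rng, clean.shape[0], clean.shape[1])
            if cfg.mixing is not None:
                noise = np.asarray(cfg.mixing) @ noise
            rms_clean = np.sqrt(np.mean(clean[active] ** 2))
            rms_noise = np.sqrt(np.mean(noise[active] ** 2))
            data = clean + noise * (rms_clean / (cfg.snr * rms_noise))
        trials.append(data)
        events.append(ev)
    return TrialSet(
        data=np.stack(trials, axis=-1),
        fs=cfg.fs,
        cues=cues,
        channel_names=list(cfg.channel_names),
        events=events if spec.kind == "p300" else None,
        paradigm=spec.kind,
    )


def simulate_accuracy(kind: str, snr: float, seed: int,
                      rule: str = "max", length=None,
                      train_cues: int | None = None,
                      test_cues: int | None = None,
                      ridge: float = 0.0, noise: str = "pink",
                      spec: ParadigmSpec | None = None) -> float:
    """Train on one synthetic session, decode a fresh test session.

    ``train_cues``/``test_cues`` override the preset cues-per-target count
    (the preset is the study protocol; overrides scale the simulation).
    Returns the fraction of correctly decoded test trials.
    """
    from .decode import fit_classifier, predict_max  # local import, no cycle at module load

    base = spec if spec is not None else get_spec(kind)
    kind = base.kind
    seed = int(seed) % (2 ** 31 - 1)

    def _session(cues_per_target, s):
        sp = base if cues_per_target is None else ParadigmSpec(
            **{**base.__dict__, "cues_per_target": cues_per_target})
        cfg = SynthConfig(spec=sp, snr=snr, seed=s, noise=noise)
        return condition_trials(generate_session(cfg)), sp

    train, sp_train = _session(train_cues, seed)
    test, _ = _session(test_cues, seed + 1_000_003)
    fitted = fit_paradigm(train, sp_train, ridge=ridge)
    feats = trialset_features(test, fitted, length=length)
    if rule == "max":
        pred = np.array([predict_max(f) for f in feats])
    else:
        train_feats = trialset_features(train, fitted, length=length)
        clf = fit_classifier(rule, train_feats, train.cues, seed=seed)
        pred = clf.predict(feats).astype(int)
    return float(np.mean(pred == test.cues))


def snr_sweep(kind: str, snr_grid, n_runs: int = 5, seed: int = 0,
              rule: str = "max", length=None,
              train_cues: int | None = None,
              test_cues: int | None = None) -> pd.DataFrame:
    """Decoding accuracy versus SNR: mean and sd over seeded runs."""
    rows = []
    for snr in snr_grid:
        accs = [simulate_accuracy(kind, snr, seed + 7919 * run, rule=rule,
                                  length=length, train_cues=train_cues,
                                  test_cues=test_cues)
                for run in range(n_runs)]
        rows.append(dict(paradigm=kind, rule=rule, snr=snr,
                         mean_accuracy=float(np.mean(accs)),
                         sd_accuracy=float(np.std(accs, ddof=1)) if n_runs > 1 else 0.0,
                         n_runs=n_runs))
    return pd.DataFrame(rows)
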