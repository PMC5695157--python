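"""Plain-text on-disk formats for sessions, recordings, weights, results.

A session directory holds ``meta.yaml`` (paradigm, rates, channels, cues),
one CSV per trial (samples x channels) and an ``events.csv`` table with
0-based integer sample indices at the data's own rate.  Floats are written
with 17 significant digits so every round trip is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import TrialSet
from .core import BeamformerWeights, SpatiotemporalPattern
from .paradigms import FittedBeamformers, get_spec
from .preprocess import RawRecording

__all__ = [
    "write_session", "read_session",
    "write_recording", "read_recording",
    "write_weights", "read_weights",
    "write_results", "read_results",
]

_FMT = "%.17g"  # exact float64 round trip


def _write_matrix(path: Path, arr: np.ndarray, header: str) -> None:
    np.savetxt(path, arr, fmt=_FMT, delimiter=",", header=header, comments="")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))


def write_session(ts: TrialSet, path) -> Path:
    """Write a :class:`TrialSet` to a session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(
        format="stbf-session-v1",
        paradigm=ts.paradigm,
        fs=float(ts.fs),
        channel_names=list(ts.channel_names),
        n_trials=int(ts.n_trials),
        n_samples=int(ts.n_samples),
        cues=[int(c) for c in ts.cues],
    )
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    header = ",".join(ts.channel_names)
    for k in range(ts.n_trials):
        _write_matrix(path / f"trial_{k:04d}.csv", ts.data[:, :, k].T, header)
    rows = []
    if ts.events is not None:
        for k, ev in enumerate(ts.events):
            for sample, code in ev:
                rows.append((k, int(sample), int(code)))
    pd.DataFrame(rows, columns=["trial", "sample_index", "code"]).to_csv(
        path / "events.csv", index=False)
    return path


def read_session(path) -> TrialSet:
    """Read a session directory back into a :class:`TrialSet`."""
    path = Path(path)
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    n_trials = meta["n_trials"]
    data = np.stack(
        [_read_matrix(path / f"trial_{k:04d}.csv").T for k in range(n_trials)],
        axis=-1)
    ev_table = pd.read_csv(path / "events.csv")
    events = None
    if len(ev_table):
        events = [ev_table[ev_table.trial == k][["sample_index", "code"]]
                  .to_numpy(dtype=int) for k in range(n_trials)]
    return TrialSet(data=data, fs=meta["fs"], cues=np.array(meta["cues"], dtype=int),
                    channel_names=list(meta["channel_names"]), events=events,
                    paradigm=meta["paradigm"])


def write_recording(rec: RawRecording, path) -> Path:
    """Write a continuous :class:`RawRecording` (data.csv + events.csv + meta)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(dict(format="stbf-recording-v1", fs=float(rec.fs),
                            channel_names=list(rec.channel_names)), fh,
                       sort_keys=False)
    _write_matrix(path / "data.csv", rec.data.T, ",".join(rec.channel_names))
    pd.DataFrame(rec.events, columns=["sample_index", "code"]).to_csv(
        path / "events.csv", index=False)
    return path


def read_recording(path, montage: list[str] | None = None) -> RawRecording:
    """Read a recording directory, optionally selecting a channel montage.

    Raises a :class:`ValueError` naming any requested channel that the
    recording does not contain.
    """
    path = Path(path)
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    names = list(meta["channel_names"])
    data = _read_matrix(path / "data.csv").T
    ev_table = pd.read_csv(path / "events.csv")
    events = ev_table[["sample_index", "code"]].to_numpy(dtype=int)
    if montage is not None:
        missing = [c for c in montage if c not in names]
        if missing:
            raise ValueError(f"montage channel(s) missing from recording: {missing}")
        data = data[[names.index(c) for c in montage]]
        names = list(montage)
    return RawRecording(data=data, fs=meta["fs"], channel_names=names, events=events)


def write_weights(fitted: FittedBeamformers, path) -> Path:
    """Write a fitted pattern/weight bundle to a directory of CSV matrices."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(
        format="stbf-weights-v1",
        paradigm=fitted.spec.kind,
        n_targets=int(fitted.spec.n_targets),
        length=fitted.length,
        beamformers=[dict(label=str(p.label), m=int(w.m), n=int(w.n),
                          constraint_residual=float(w.constraint_residual),
                          used_pinv=bool(w.used_pinv))
                     for p, w in zip(fitted.patterns, fitted.weights)],
    )
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for i, (p, w) in enumerate(zip(fitted.patterns, fitted.weights)):
        _write_matrix(path / f"pattern_{i:03d}.csv", p.pattern, "pattern")
        _write_matrix(path / f"weights_{i:03d}.csv", w.w[None, :], "w")
    return path


def read_weights(path) -> FittedBeamformers:
    """Read a pattern/weight bundle written by :func:`write_weights`."""
    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    spec = get_spec(meta["paradigm"])
    if meta["n_targets"] != spec.n_targets:
        raise ValueError("weight bundle was fitted with a non-preset target count; "
                         "re-fit from data instead")
    patterns, weights = [], []
    for i, info in enumerate(meta["beamformers"]):
        pat = _read_matrix(path / f"pattern_{i:03d}.csv")
        w = _read_matrix(path / f"weights_{i:03d}.csv").ravel()
        label: object = info["label"]
        patterns.append(SpatiotemporalPattern(pattern=pat, label=label))
        weights.append(BeamformerWeights(
            w=w, m=info["m"], n=info["n"], pattern_ref=label,
            constraint_residual=info["constraint_residual"],
            used_pinv=info["used_pinv"]))
    return FittedBeamformers(spec=spec, patterns=patterns, weights=weights,
                             covariance_dims=[w.m * w.n for w in weights],
                             length=meta["length"])


def write_results(table: pd.DataFrame, path) -> Path:
    """Write a tidy results table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
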