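"""Shared data containers for sessions and labeled trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MONTAGE = ["Fz", "Cz", "Pz", "Oz", "O1", "O2", "PO3", "PO4", "P3", "P4"]

__all__ = ["TrialSet", "DEFAULT_MONTAGE"]


@dataclass
class TrialSet:
    """Labeled multichannel trials for one paradigm.

    Parameters
    ----------
    data : ndarray, shape (m, n, r)
        m channels, n samples per trial, r trials.
    fs : float
        Sampling rate in Hz.
    cues : ndarray, shape (r,)
        Cued (gazed) target index per trial, 0-based.
    channel_names : list of str
    events : list of ndarray, optional
        Per-trial event tables, each (k, 2) int rows of
        (sample_index_within_trial, code).  Used by the serial-highlight
        paradigm, where the code is the highlighted target index.
    paradigm : str
        One of ``"p300"``, ``"ssvep"``, ``"cvep"``.
    """

    data: np.ndarray
    fs: float
    cues: np.ndarray
    channel_names: list[str]
    events: list[np.ndarray] | None = None
    paradigm: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.cues = np.asarray(self.cues, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        if self.cues.shape != (self.data.shape[2],):
            raise ValueError("cues must have one entry per trial")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        if self.events is not None:
            if len(self.events) != self.n_trials:
                raise ValueError("events must have one table per trial")
            self.events = [np.asarray(e, dtype=int).reshape(-1, 2) for e in self.events]

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "TrialSet":
        """Select trials by index array (copies)."""
        idx = np.asarray(idx, dtype=int)
        return TrialSet(
            data=self.data[:, :, idx].copy(),
            fs=self.fs,
            cues=self.cues[idx].copy(),
            channel_names=list(self.channel_names),
            events=None if self.events is None else [self.events[i].copy() for i in idx],
            paradigm=self.paradigm,
        )
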