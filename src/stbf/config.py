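"""Per-paradigm presets and run-configuration handling.

The preprocessing presets mirror each study protocol: the serial-highlight
data are band-passed 0.5-15 Hz and analyzed at 64 Hz (0.6-s epochs with a
100 ms pre-onset baseline), the flicker data 4-20 Hz at 512 Hz (5-s
trials, first 120 ms skipped), and the code data 4-31 Hz at 120 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .containers import DEFAULT_MONTAGE

__all__ = ["PREPROCESS_PRESETS", "SYNTH_FS", "RunConfig", "load_config", "validate_config"]

PREPROCESS_PRESETS: dict[str, dict] = {
    "p300": {"band": (0.5, 15.0), "target_fs": 64.0,
             "epoch_seconds": 0.6, "baseline_seconds": 0.1, "folds": 4},
    "ssvep": {"band": (4.0, 20.0), "target_fs": 512.0,
              "trial_seconds": 5.0, "transient_skip": 0.12, "folds": 5},
    "cvep": {"band": (4.0, 31.0), "target_fs": 120.0, "folds": 5},
}

#: default generator rates — integer multiples of each analysis rate
SYNTH_FS: dict[str, float] = {"p300": 256.0, "ssvep": 512.0, "cvep": 360.0}

_KNOWN_KEYS = {
    "paradigm", "montage", "ridge", "rules", "folds", "lengths", "seed",
    "snr", "noise", "data", "out",
}


@dataclass
class RunConfig:
    """Validated evaluation-run configuration."""

    paradigm: str
    montage: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    ridge: float = 0.0
    rules: list[str] = field(default_factory=lambda: ["max"])
    folds: int | None = None
    lengths: list | None = None
    seed: int = 0
    snr: float = 0.25
    noise: str = "pink"
    data: str | None = None
    out: str | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PREPROCESS_PRESETS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.lengths is not None:
            if any(l <= 0 for l in self.lengths):
                raise ValueError("lengths must be positive")
            if sorted(self.lengths) != list(self.lengths):
                raise ValueError("lengths must be sorted ascending")


def validate_config(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig`, rejecting unknown keys by name."""
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    if "paradigm" not in raw:
        raise ValueError("configuration requires a 'paradigm' key")
    return RunConfig(**raw)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must hold a mapping")
    return validate_config(raw)
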