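"""Maximum-length binary sequences (m-sequences) via LFSR.

An m-sequence of degree d is generated by a linear feedback shift register
with a primitive feedback polynomial; its period is 2^d - 1, it is balanced
(2^(d-1) ones), and the circular autocorrelation of its +/-1 mapping equals
-1 at every nonzero lag — the property that makes lagged copies of one
sequence nearly orthogonal stimulus codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MSequence", "generate_msequence"]


@dataclass
class MSequence:
    """Binary m-sequence with its generator description."""

    bits: np.ndarray
    degree: int
    taps: tuple[int, ...]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def signed(self) -> np.ndarray:
        """+/-1 mapping (1 -> +1, 0 -> -1)."""
        return 2 * self.bits - 1

    def circular_autocorrelation(self) -> np.ndarray:
        """Normalized circular autocorrelation of the signed sequence."""
        s = self.signed
        n = s.size
        return np.array([int(s @ np.roll(s, k)) for k in range(n)])


def generate_msequence(degree: int = 6, taps: tuple[int, ...] = (6, 5),
                       seed_state: int | None = None) -> MSequence:
    """Generate a maximum-length sequence from an LFSR.

    Parameters
    ----------
    degree : int
        Register length d; the sequence has length 2^d - 1.
    taps : tuple of int
        Exponents of the feedback polynomial with nonzero coefficients
        (the x^0 term is implicit), e.g. ``(6, 5)`` for x^6 + x^5 + 1.
    seed_state : int, optional
        Initial register contents (nonzero); defaults to all ones.  Only
        rotates the sequence.

    Raises
    ------
    ValueError
        If the taps are not primitive, i.e. the register state period is
        shorter than 2^d - 1.
    """
    if degree < 2:
        raise ValueError("degree must be >= 2")
    if max(taps) != degree or min(taps) < 1:
        raise ValueError("taps must include the degree and be within [1, degree]")
    period = (1 << degree) - 1
    state = (seed_state if seed_state is not None else period) & period
    if state == 0:
        raise ValueError("initial state must be nonzero")
    start = state
    bits = []
    for i in range(period):
        out = state & 1
        bits.append(out)
        fb = 0
        for t in taps:
            fb ^= (state >> (degree - t)) & 1
        state = (state >> 1) | (fb << (degree - 1))
        if state == start and i != period - 1:
            raise ValueError(
                f"period shorter than 2^{degree} - 1: taps {taps} are not primitive"
            )
    if state != start:
        raise ValueError(f"period shorter than 2^{degree} - 1: taps {taps} are not primitive")
    return MSequence(bits=np.array(bits, dtype=int), degree=degree, taps=tuple(taps))
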