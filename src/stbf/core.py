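"""Closed-form spatiotemporal LCMV beamforming.

The linearly constrained minimum variance (LCMV) beamformer is a linear
filter ``w`` that minimizes the output variance ``w' Sigma w`` subject to
unit gain on a known activation pattern ``a`` (``a' w = 1``).  In its
spatiotemporal form the pattern is a full channels x samples template of the
evoked response: each EEG segment ``S`` (m channels, n samples) is flattened
channel-major into a length m*n row, the covariance ``Sigma`` is pooled over
all available segments, and the filter output

    y = flat(S) . w,    w = Sigma^{-1} a / (a' Sigma^{-1} a)

estimates how strongly the template is expressed in ``S``.  The constraint
makes the output calibrated: a segment equal to the template itself yields
exactly y = 1.

This module holds the segment containers and the four primitive operations
(flatten, covariance estimation, weight computation, filter application);
paradigm-specific template construction lives in :mod:`stbf.paradigms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentStack",
    "FlattenedSegments",
    "SpatiotemporalPattern",
    "PooledCovariance",
    "BeamformerWeights",
    "flatten_segments",
    "unflatten_segments",
    "estimate_covariance",
    "lcmv_weights",
    "spatial_lcmv_weights",
    "apply_beamformer",
]


@dataclass
class SegmentStack:
    """A stack of r equally shaped EEG segments.

    Parameters
    ----------
    data : ndarray, shape (m, n, r)
        m channels, n samples per segment, r segments.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One label per channel, in row order.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SegmentStack data must be (channels, samples, segments)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def r(self) -> int:
        return self.data.shape[2]


@dataclass
class FlattenedSegments:
    """r x (m*n) matrix of channel-major flattened segments."""

    rows: np.ndarray
    m: int
    n: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != self.m * self.n:
            raise ValueError("rows must be (r, m*n)")


@dataclass
class SpatiotemporalPattern:
    """Activation pattern A (channels x samples) for one signal-of-interest."""

    pattern: np.ndarray
    label: object = None

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be 2-D (channels, samples)")

    @property
    def flat(self) -> np.ndarray:
        """Channel-major flattening a of A (row-wise concatenation)."""
        return self.pattern.ravel()

    @property
    def shape(self) -> tuple[int, int]:
        return self.pattern.shape


@dataclass
class PooledCovariance:
    """(m*n) x (m*n) sample covariance of flattened segments.

    ``ridge`` is an absolute diagonal loading term; it is stored here and
    applied only when the matrix is inverted, so the estimate itself stays
    unbiased.
    """

    sigma: np.ndarray
    n_segments: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise ValueError("sigma must be square")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")

    @property
    def dim(self) -> int:
        return self.sigma.shape[0]


@dataclass
class BeamformerWeights:
    """LCMV weight vector with its constraint diagnostics.

    ``constraint_residual`` is |a'w - 1|; ``used_pinv`` flags that the
    covariance was (numerically) singular and a pseudo-inverse was used.
    """

    w: np.ndarray
    m: int
    n: int
    pattern_ref: object = None
    constraint_residual: float = 0.0
    used_pinv: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size != self.m * self.n:
            raise ValueError("weight length must equal m*n")


def flatten_segments(stack: SegmentStack) -> FlattenedSegments:
    """Flatten an (m, n, r) stack into an r x (m*n) matrix X.

    Row l is the channel-major concatenation of segment l: channel 1's n
    samples, then channel 2's, and so on.  The round trip through
    :func:`unflatten_segments` is exact.
    """
    if stack.r == 0:
        raise ValueError("no segments")
    m, n, r = stack.m, stack.n, stack.r
    rows = np.transpose(stack.data, (2, 0, 1)).reshape(r, m * n)
    return FlattenedSegments(rows=rows.copy(), m=m, n=n)


def unflatten_segments(flat: FlattenedSegments, fs: float = 1.0,
                       channel_names: list[str] | None = None) -> SegmentStack:
    """Inverse of :func:`flatten_segments`."""
    r = flat.rows.shape[0]
    data = flat.rows.reshape(r, flat.m, flat.n).transpose(1, 2, 0)
    return SegmentStack(data=data.copy(), fs=fs, channel_names=channel_names)


def estimate_covariance(flat: FlattenedSegments, ridge: float = 0.0) -> PooledCovariance:
    """Sample covariance of the flattened segment rows.

    Mean-subtracted across the r rows, normalized by (r - 1).  The ridge is
    stored, not baked into the matrix.
    """
    rows = flat.rows
    if rows.shape[0] < 2:
        raise ValueError("insufficient segments: need r >= 2 for a covariance estimate")
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite values in segments")
    sigma = np.atleast_2d(np.cov(rows, rowvar=False, ddof=1))
    return PooledCovariance(sigma=sigma, n_segments=rows.shape[0], ridge=float(ridge))


def _solve_lcmv(sigma: np.ndarray, ridge: float, a: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return (Sigma + ridge I)^{-1} a, with a pseudo-inverse fallback.

    With ridge = 0 the (symmetric) matrix is eigendecomposed and treated as
    singular when its numerical rank falls short of its dimension
    (eigenvalues below dim * eps relative to the largest are noise at
    working precision); the inverse is then restricted to the retained
    eigenspace — a plain solve on such a matrix would amplify float noise
    into the weights.  When even the pseudo-inverse leaves the constraint
    direction with zero response (e.g. a zero covariance), the
    minimum-norm feasible solution direction ``a`` is returned, since
    every feasible vector then attains the same (zero) output variance.
    """
    dim = sigma.shape[0]
    if ridge > 0:
        mat = sigma + ridge * np.eye(dim)
        try:
            x = np.linalg.solve(mat, a)
            if np.all(np.isfinite(x)):
                return x, False
        except np.linalg.LinAlgError:
            pass
    sym = (sigma + sigma.T) / 2.0 + ridge * np.eye(dim)
    vals, vecs = np.linalg.eigh(sym)
    cutoff = dim * np.finfo(float).eps * max(vals.max(), 0.0)
    keep = vals > cutoff
    used_pinv = not keep.all()
    inv_vals = np.where(keep, 1.0 / np.where(keep, vals, 1.0), 0.0)
    x = vecs @ (inv_vals * (vecs.T @ a))
    return x, used_pinv


def lcmv_weights(cov: PooledCovariance, pattern: SpatiotemporalPattern) -> BeamformerWeights:
    """LCMV weights w = Sigma^{-1} a / (a' Sigma^{-1} a).

    w satisfies a'w = 1 and minimizes w' Sigma w among all vectors meeting
    that constraint.  Inversion uses sigma + ridge*I; a singular matrix with
    ridge = 0 falls back to the pseudo-inverse (flagged on the result).
    """
    a = pattern.flat
    if a.size != cov.dim:
        raise ValueError(
            f"dimension mismatch: pattern has {a.size} elements, covariance is {cov.dim}x{cov.dim}"
        )
    if not np.any(a):
        raise ValueError("unconstrained: activation pattern is all-zero")
    x, used_pinv = _solve_lcmv(cov.sigma, cov.ridge, a)
    denom = float(a @ x)
    if abs(denom) <= 1e-14 * float(a @ a):
        if not used_pinv:
            raise ValueError("unconstrained: a' Sigma^{-1} a is zero")
        # degenerate pseudo-inverse path: all feasible vectors are optimal
        w = a / float(a @ a)
        used_pinv = True
    else:
        w = x / denom
    residual = abs(float(a @ w) - 1.0)
    m, n = pattern.shape
    return BeamformerWeights(w=w, m=m, n=n, pattern_ref=pattern.label,
                             constraint_residual=residual, used_pinv=used_pinv)


def spatial_lcmv_weights(cov_sp: np.ndarray, a_sp: np.ndarray,
                         ridge: float = 0.0) -> np.ndarray:
    """Spatial LCMV weights w = Sigma_sp^{-1} a_sp / (a_sp' Sigma_sp^{-1} a_sp).

    Identical to :func:`lcmv_weights` with a single time sample (n = 1);
    provided for parity and testing.
    """
    a_sp = np.asarray(a_sp, dtype=float).ravel()
    cov = PooledCovariance(sigma=np.asarray(cov_sp, dtype=float),
                           n_segments=0, ridge=ridge)
    pattern = SpatiotemporalPattern(pattern=a_sp[:, None])
    return lcmv_weights(cov, pattern).w


def apply_beamformer(weights: BeamformerWeights, segment: np.ndarray) -> float:
    """Filter output y = flat(S) . w for one (m, n) segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape != (weights.m, weights.n):
        raise ValueError(
            f"dimension mismatch: segment is {segment.shape}, weights expect {(weights.m, weights.n)}"
        )
    return float(segment.ravel() @ weights.w)
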