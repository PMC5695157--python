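"""Model/Results interface over the beamformer pipeline.

``BeamformerDecoder`` is constructed from a labeled
:class:`~stbf.containers.TrialSet` and a :class:`~stbf.paradigms.ParadigmSpec`;
``fit()`` estimates the activation pattern(s), pooled covariance(s) and LCMV
weight vector(s) and returns a :class:`BeamformerDecoderResults` carrying
them together with constraint diagnostics, a ``summary()`` table, and
``transform`` / ``predict`` / ``score`` methods for new trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import TrialSet
from .decode import RULES, cross_validate, fit_classifier, predict_max
from .paradigms import FittedBeamformers, ParadigmSpec, fit_paradigm, get_spec, trialset_features

__all__ = ["BeamformerDecoder", "BeamformerDecoderResults"]


class BeamformerDecoder:
    """Spatiotemporal LCMV decoder for one synchronous BCI paradigm.

    Parameters
    ----------
    data : TrialSet
        Training trials at the analysis rate (see
        :func:`stbf.preprocess.condition_trials`).
    spec : ParadigmSpec, optional
        Defaults to the preset matching ``data.paradigm``.
    ridge : float
        Diagonal loading added to the pooled covariance at inversion.
    """

    def __init__(self, data: TrialSet, spec: ParadigmSpec | None = None,
                 ridge: float = 0.0):
        if spec is None:
            spec = get_spec(data.paradigm)
        if spec.kind != data.paradigm and data.paradigm:
            raise ValueError("spec kind does not match data paradigm")
        self.data = data
        self.spec = spec
        self.ridge = float(ridge)

    @classmethod
    def from_session(cls, session: TrialSet, **kwargs) -> "BeamformerDecoder":
        """Build from a raw generator session, conditioning it first."""
        from .preprocess import condition_trials

        return cls(condition_trials(session), **kwargs)

    def fit(self, length=None) -> "BeamformerDecoderResults":
        """Estimate patterns, covariance(s) and weights on the training set.

        ``length`` restricts the training trials to an evaluated
        stimulation length (highlight/code repetitions, or seconds for the
        flicker paradigm).
        """
        fitted = fit_paradigm(self.data, self.spec, ridge=self.ridge, length=length)
        return BeamformerDecoderResults(self, fitted)

    def cross_validate(self, rules=("max",), lengths=None, n_folds=None,
                       seed: int = 0, **kwargs):
        """Stratified k-fold evaluation; see :func:`stbf.decode.cross_validate`."""
        return cross_validate(self.data, self.spec, rules=rules, lengths=lengths,
                              n_folds=n_folds, seed=seed, ridge=self.ridge, **kwargs)


class BeamformerDecoderResults:
    """Fitted patterns, weights and diagnostics of a :class:`BeamformerDecoder`."""

    def __init__(self, model: BeamformerDecoder, fitted: FittedBeamformers):
        self.model = model
        self.fitted = fitted
        self.patterns = fitted.patterns
        self.weights = fitted.weights
        self._classifiers: dict[str, object] = {}

    @property
    def constraint_residuals(self) -> np.ndarray:
        """|a'w - 1| per beamformer."""
        return np.array([w.constraint_residual for w in self.weights])

    def transform(self, data: TrialSet | None = None, length=None) -> np.ndarray:
        """Beamformer-output feature matrix (n_trials, n_targets)."""
        ts = data if data is not None else self.model.data
        return trialset_features(ts, self.fitted, length=length)

    def predict(self, data: TrialSet | None = None, rule: str = "max",
                length=None) -> np.ndarray:
        """Decoded target index per trial under the given prediction rule."""
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}")
        feats = self.transform(data, length=length)
        if rule == "max":
            return np.array([predict_max(f) for f in feats])
        if rule not in self._classifiers:
            train = self.transform(self.model.data, length=length)
            self._classifiers[rule] = fit_classifier(rule, train, self.model.data.cues)
        return self._classifiers[rule].predict(feats).astype(int)

    def score(self, data: TrialSet, rule: str = "max", length=None) -> float:
        """Decoding accuracy on labeled trials."""
        return float(np.mean(self.predict(data, rule=rule, length=length) == data.cues))

    def summary(self) -> str:
        """Human-readable fit summary (one row per target beamformer)."""
        spec = self.model.spec
        rows = []
        for i, (p, w) in enumerate(zip(self.patterns, self.weights)):
            rows.append(dict(
                target=p.label if p.label is not None else i,
                pattern_shape=f"{p.shape[0]}x{p.shape[1]}",
                cov_dim=w.m * w.n,
                pattern_rms=float(np.sqrt(np.mean(p.pattern ** 2))),
                weight_norm=float(np.linalg.norm(w.w)),
                constraint_residual=w.constraint_residual,
                pinv=w.used_pinv,
            ))
        table = pd.DataFrame(rows)
        head = (
            f"Spatiotemporal LCMV beamformer decoder\n"
            f"  paradigm: {spec.kind}   targets: {spec.n_targets}   "
            f"trials: {self.model.data.n_trials}   fs: {self.model.data.fs:g} Hz\n"
            f"  ridge: {self.model.ridge:g}   "
            f"training length: {self.fitted.length if self.fitted.length is not None else 'full'}\n"
        )
        return head + table.to_string(index=False, float_format=lambda v: f"{v:.4g}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<BeamformerDecoderResults: {self.model.spec.kind}, "
                f"{len(self.weights)} beamformer(s)>")
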