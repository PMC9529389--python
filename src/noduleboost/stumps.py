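"""Decision stumps: the minimal weighted base learner.

A stump thresholds one feature and predicts ±1 with one of two polarities.
It exists so the boosting arithmetic can be exercised and verified exactly,
free of the stochasticity of network training; it satisfies the same
fit/predict_hard protocol as the SNMV-CNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DecisionStump"]


@dataclass
class DecisionStump:
    """Exhaustive-search weighted decision stump on flat feature vectors.

    Predicts ``polarity`` where feature > threshold and ``-polarity``
    elsewhere; fit scans every midpoint threshold of every feature and both
    polarities, minimizing weighted 0-1 error.  Ties keep the first
    (feature, threshold, polarity) found, a fixed deterministic order.
    """

    feature: int = 0
    threshold: float = 0.0
    polarity: int = 1

    def fit(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        sample_weights: np.ndarray | None = None,
    ) -> "DecisionStump":
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        x2d = x.reshape(x.shape[0], -1)
        labels = np.asarray(labels)
        n = len(labels)
        w = (
            np.full(n, 1.0 / n)
            if sample_weights is None
            else np.asarray(sample_weights, dtype=np.float64) / np.sum(sample_weights)
        )
        best = (np.inf, 0, 0.0, 1)
        for j in range(x2d.shape[1]):
            vals = np.unique(x2d[:, j])
            cuts = np.concatenate(
                ([vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0])
            )
            for t in cuts:
                above = x2d[:, j] > t
                for pol in (1, -1):
                    pred = np.where(above, pol, -pol)
                    err = w[pred != labels].sum()
                    if err < best[0] - 1e-15:
                        best = (err, j, float(t), pol)
        _, self.feature, self.threshold, self.polarity = best
        return self

    def predict_hard(self, x: np.ndarray) -> np.ndarray:
        x2d = np.asarray(x, dtype=np.float64).reshape(np.asarray(x).shape[0], -1)
        return np.where(
            x2d[:, self.feature] > self.threshold, self.polarity, -self.polarity
        )

    def to_dict(self) -> dict:
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "polarity": int(self.polarity),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionStump":
        return cls(**d)
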