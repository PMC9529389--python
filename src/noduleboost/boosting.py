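"""Base-learner-agnostic AdaBoost engine.

Classic discrete AdaBoost over ±1 labels: a distribution S_m over the n
training samples starts uniform at 1/n; each round trains a base learner
under the current weights, measures its weighted training error

    eps_m = sum_i S_m(i) * 1[f_m(x_i) != c_i],

converts it to a log-odds vote

    d_m = 0.5 * ln((1 - eps_m) / eps_m),

and reweights multiplicatively,

    S_{m+1}(i) = S_m(i) * exp(-d_m * c_i * f_m(x_i)) / Z_m,

with Z_m the normalizer keeping S a distribution — correctly classified
samples shrink, mistakes grow, so the next learner concentrates on what its
predecessors got wrong.  Inference combines the learners' hard predictions
by the weighted vote F(x) = sign(sum_m d_m f_m(x)); the unsquashed sum is
the margin score used for ROC analysis.  A simple (unweighted majority)
voting scheme is also provided.

Any object with ``fit(X, labels, sample_weights)`` and ``predict_hard(X)``
can serve as a base learner; the SNMV-CNN and an in-repo decision stump both
satisfy the protocol.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "EPSILON_CLAMP",
    "BoostRound",
    "EnsembleModel",
    "init_weights",
    "weighted_error",
    "voting_weight",
    "update_weights",
    "fit_ensemble",
    "predict_ensemble",
    "training_error_bound",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger(__name__)

#: Symmetric clamp keeping the vote d_m finite at eps in {0, 1}.
EPSILON_CLAMP = 1e-10

WEIGHT_SUM_TOL = 1e-12


class BaseLearner(Protocol):
    def fit(
        self, x: np.ndarray, labels: np.ndarray, sample_weights: np.ndarray | None
    ) -> "BaseLearner": ...

    def predict_hard(self, x: np.ndarray) -> np.ndarray: ...


def _check_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0):
        raise ValueError("sample weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"sample weights must sum to 1, got {weights.sum()!r}")
    return weights


def _check_pm1(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.all(np.isin(v, (-1, 1))):
        raise ValueError(f"{name} must be ±1 valued")
    return v


def init_weights(n: int) -> np.ndarray:
    """Uniform distribution 1/n over n samples."""
    if n < 1:
        raise ValueError("need at least one sample")
    return np.full(n, 1.0 / n)


def weighted_error(
    predictions: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> float:
    """Weight mass on the misclassified samples."""
    predictions = _check_pm1(predictions, "predictions")
    labels = _check_pm1(labels, "labels")
    weights = _check_weights(weights)
    if not (len(predictions) == len(labels) == len(weights)):
        raise ValueError(
            f"length mismatch: predictions {len(predictions)}, labels "
            f"{len(labels)}, weights {len(weights)}"
        )
    return float(weights[predictions != labels].sum())


def voting_weight(epsilon: float, clamp: float = EPSILON_CLAMP) -> float:
    """Log-odds vote 0.5*ln((1-eps)/eps), with eps clamped into
    [clamp, 1-clamp] so the vote stays finite; positive iff eps < 0.5."""
    eps = min(max(float(epsilon), clamp), 1.0 - clamp)
    return float(0.5 * np.log((1.0 - eps) / eps))


def update_weights(
    weights: np.ndarray,
    d: float,
    labels: np.ndarray,
    predictions: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Multiplicative reweighting; returns (new weights, normalizer Z).

    Each weight is multiplied by exp(-d * c_i * f_i) and renormalized:
    correct samples (c_i f_i = +1) shrink, mistakes grow (for d > 0).
    """
    weights = _check_weights(weights)
    labels = _check_pm1(labels, "labels")
    predictions = _check_pm1(predictions, "predictions")
    if not (len(weights) == len(labels) == len(predictions)):
        raise ValueError("weights, labels, predictions must share a length")
    if d == 0.0:  # exp(0) = 1 and Z = 1: exact identity
        return weights.copy(), 1.0
    unnormalized = weights * np.exp(-d * labels * predictions)
    z = float(unnormalized.sum())
    assert z > 0, "normalizer vanished despite finite vote"
    return unnormalized / z, z


@dataclass(frozen=True)
class BoostRound:
    """Bookkeeping of one boosting iteration."""

    round_index: int
    epsilon: float  # weighted error, after clamping
    vote: float  # d_m = 0.5 ln((1-eps)/eps)
    normalizer: float  # Z_m
    learner: object

    def __post_init__(self) -> None:
        if self.normalizer <= 0:
            raise ValueError("normalizer must be positive")


@dataclass
class EnsembleModel:
    """Ordered boosted rounds plus the voting scheme used at inference."""

    rounds: list[BoostRound]
    voting_scheme: str = "weighted"

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("ensemble needs at least one round")
        if self.voting_scheme not in ("weighted", "simple"):
            raise ValueError(f"unknown voting scheme {self.voting_scheme!r}")

    @property
    def votes(self) -> np.ndarray:
        return np.array([r.vote for r in self.rounds])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([r.epsilon for r in self.rounds])


def fit_ensemble(
    x: np.ndarray,
    labels: np.ndarray,
    n_rounds: int,
    learner_factory: Callable[[int, int], BaseLearner],
    seed: int = 0,
    epsilon_policy: str = "continue",
    voting_scheme: str = "weighted",
) -> EnsembleModel:
    """Run the boosting loop for ``n_rounds`` rounds.

    ``learner_factory(round_index, round_seed)`` must return a fresh base
    learner; round seeds are derived deterministically from ``seed`` so the
    whole fit replays bit-for-bit.  A round with weighted error >= 0.5 gets a
    non-positive vote; ``epsilon_policy`` chooses between keeping it and
    continuing (default, fixed-round-count semantics) and stopping early.

    Parameters
    ----------
    x : array, first axis = samples (patch stacks or plain features)
    labels : ±1 vector with both classes present
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if epsilon_policy not in ("continue", "stop"):
        raise ValueError(f"unknown epsilon policy {epsilon_policy!r}")
    labels = _check_pm1(np.asarray(labels), "labels")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    n = len(labels)
    round_seeds = np.random.SeedSequence(seed).generate_state(n_rounds) % (2**31)

    weights = init_weights(n)
    rounds: list[BoostRound] = []
    for m in range(n_rounds):
        learner = learner_factory(m, int(round_seeds[m]))
        learner.fit(x, labels, sample_weights=weights)
        preds = _check_pm1(learner.predict_hard(x), "base-learner predictions")
        eps = weighted_error(preds, labels, weights)
        eps_clamped = min(max(eps, EPSILON_CLAMP), 1.0 - EPSILON_CLAMP)
        d = voting_weight(eps)
        weights, z = update_weights(weights, d, labels, preds)
        rounds.append(BoostRound(m, eps_clamped, d, z, learner))
        logger.info("boost round %d: eps=%.4f d=%.4f Z=%.4f", m, eps, d, z)
        if eps >= 0.5:
            warnings.warn(
                f"boosting round {m} has weighted error {eps:.3f} >= 0.5 "
                f"(policy: {epsilon_policy})",
                stacklevel=2,
            )
            if epsilon_policy == "stop":
                break
    return EnsembleModel(rounds=rounds, voting_scheme=voting_scheme)


def predict_ensemble(
    ensemble: EnsembleModel, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Combine the rounds' hard predictions; returns (labels, margins).

    Weighted scheme: margin = sum_m d_m f_m(x).  Simple scheme: unweighted
    majority, margin = sum_m f_m(x).  A margin of exactly 0 maps to +1.
    The margin doubles as the continuous score for ROC analysis.
    """
    preds = np.stack([r.learner.predict_hard(x) for r in ensemble.rounds])
    if ensemble.voting_scheme == "weighted":
        margins = ensemble.votes @ preds
    else:
        margins = preds.sum(axis=0).astype(np.float64)
    hard = np.where(margins >= 0, 1, -1)
    return hard, margins


def training_error_bound(epsilons: Sequence[float]) -> float:
    """Prod_m 2*sqrt(eps_m(1-eps_m)): the classic upper bound on the
    weighted-vote ensemble's training error; non-increasing in rounds."""
    eps = np.asarray(epsilons, dtype=np.float64)
    return float(np.prod(2.0 * np.sqrt(eps * (1.0 - eps))))


# ---------------------------------------------------------------------------
# serialization (directory: ensemble.json + one checkpoint per round)


def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> Path:
    """Write ensemble.json plus per-round learner checkpoints.

    Learners must expose either ``to_dict()`` (stump-style, stored inline)
    or the network checkpoint protocol (stored as round<m>.npz/.json).
    """
    from . import network, stumps

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"voting_scheme": ensemble.voting_scheme, "rounds": []}
    for r in ensemble.rounds:
        entry = {
            "round_index": r.round_index,
            "epsilon": r.epsilon,
            "vote": r.vote,
            "normalizer": r.normalizer,
        }
        if hasattr(r.learner, "to_dict"):
            entry["learner"] = {"kind": "stump", "state": r.learner.to_dict()}
        else:
            stem = out_dir / f"round{r.round_index}"
            network.save_checkpoint(r.learner, stem)
            entry["learner"] = {"kind": "snmv_cnn", "checkpoint": stem.name}
        meta["rounds"].append(entry)
    (out_dir / "ensemble.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out_dir


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    from . import network, stumps

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "ensemble.json").read_text())
    rounds = []
    for entry in meta["rounds"]:
        ld = entry["learner"]
        if ld["kind"] == "stump":
            learner = stumps.DecisionStump.from_dict(ld["state"])
        else:
            learner = network.load_checkpoint(in_dir / ld["checkpoint"])
        rounds.append(
            BoostRound(
                entry["round_index"],
                entry["epsilon"],
                entry["vote"],
                entry["normalizer"],
                learner,
            )
        )
    return EnsembleModel(rounds=rounds, voting_scheme=meta["voting_scheme"])
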