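"""Run configuration: one document tying every stage together.

A RunConfig nests the stage configs (phantom, views, learner, boosting,
evaluation) plus a single ``master_seed`` from which every stochastic
stage's seed is derived, so a serialized config reproduces a run exactly.
Round-trips losslessly through YAML.

Two named profiles ship: ``desk`` (32×32 inputs, small nets, CPU-friendly —
the default) and ``paper`` (224×224 inputs, learning rate 1e-4, batch 128 —
the full-scale settings; supported, not exercised by the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .network import BaseLearnerSpec
from .multiview import ViewConfig
from .phantom import PhantomConfig

__all__ = ["BoostingConfig", "EvaluationConfig", "RunConfig", "paper_profile"]


@dataclass(frozen=True)
class BoostingConfig:
    n_rounds: int = 3
    voting_scheme: str = "weighted"  # or "simple"
    epsilon_policy: str = "continue"  # or "stop"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EvaluationConfig:
    test_fraction: float = 0.2
    k_folds: int = 10

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    views: ViewConfig = field(default_factory=ViewConfig)
    learner: BaseLearnerSpec = field(
        default_factory=lambda: BaseLearnerSpec(
            learning_rate=3e-3, batch_size=4, epochs=3
        )
    )
    boosting: BoostingConfig = field(default_factory=BoostingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    master_seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        state = np.random.SeedSequence(self.master_seed).generate_state(4) % (2**31)
        return {
            "phantom": int(state[0]),
            "learner": int(state[1]),
            "boosting": int(state[2]),
            "split": int(state[3]),
        }

    def seeded(self) -> "RunConfig":
        """Copy with phantom/learner seeds overwritten from master_seed."""
        seeds = self.stage_seeds()
        return replace(
            self,
            phantom=replace(self.phantom, seed=seeds["phantom"]),
            learner=replace(self.learner, seed=seeds["learner"]),
        )

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "views": self.views.to_dict(),
            "learner": self.learner.to_dict(),
            "boosting": self.boosting.to_dict(),
            "evaluation": self.evaluation.to_dict(),
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            phantom=PhantomConfig.from_dict(d.get("phantom", {})),
            views=ViewConfig.from_dict(d.get("views", {})),
            learner=BaseLearnerSpec.from_dict(d.get("learner", {})),
            boosting=BoostingConfig(**d.get("boosting", {})),
            evaluation=EvaluationConfig(**d.get("evaluation", {})),
            master_seed=d.get("master_seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def paper_profile() -> RunConfig:
    """Full-scale settings: 224×224 single-channel-per-view input, Adam with
    learning rate 1e-4 and first-moment momentum 0.9, binary cross-entropy,
    batch 128.  Provided for completeness; needs far more compute than the
    desk profile."""
    return RunConfig(
        views=ViewConfig(target_size=224),
        learner=BaseLearnerSpec(
            input_size=224, learning_rate=1e-4, batch_size=128, epochs=10
        ),
    )
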