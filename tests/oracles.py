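"""Independent reference implementations used to verify the package.

Everything here is deliberately naive — explicit Python loops, scalar
arithmetic, no reuse of the package's vectorized code paths — so a match is
evidence of correctness rather than self-agreement.  The boosting
transcript does share the DecisionStump base learner with the engine: the
quantity under test is the weight/error/vote arithmetic, not the stump.
"""

from __future__ import annotations

import math

import numpy as np

from noduleboost.stumps import DecisionStump


def naive_adaboost_transcript(x, labels, n_rounds, round_seeds=None):
    """Looped, scalar AdaBoost over DecisionStump learners.

    Returns a list of dicts per round: weights_before, epsilon, d,
    weights_after (plain Python floats throughout).
    """
    n = len(labels)
    weights = [1.0 / n] * n
    transcript = []
    for _m in range(n_rounds):
        stump = DecisionStump().fit(np.asarray(x), np.asarray(labels),
                                    np.asarray(weights))
        preds = stump.predict_hard(np.asarray(x))
        eps = 0.0
        for i in range(n):
            if preds[i] != labels[i]:
                eps += weights[i]
        eps_c = min(max(eps, 1e-10), 1 - 1e-10)
        d = 0.5 * math.log((1 - eps_c) / eps_c)
        unnorm = [weights[i] * math.exp(-d * labels[i] * preds[i]) for i in range(n)]
        z = sum(unnorm)
        new_weights = [u / z for u in unnorm]
        transcript.append(
            {
                "weights_before": list(weights),
                "epsilon": eps,
                "d": d,
                "z": z,
                "weights_after": new_weights,
                "predictions": list(preds),
            }
        )
        weights = new_weights
    return transcript


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, c in zip(scores, labels) if c == 1]
    neg = [s for s, c in zip(scores, labels) if c == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def best_single_stump_error(x, labels):
    """Exhaustive search over every threshold/polarity on a 1D dataset."""
    x = list(x)
    labels = list(labels)
    n = len(x)
    cuts = sorted(set(x))
    thresholds = (
        [cuts[0] - 1]
        + [(a + b) / 2 for a, b in zip(cuts[:-1], cuts[1:])]
        + [cuts[-1] + 1]
    )
    best = 1.0
    for t in thresholds:
        for pol in (1, -1):
            err = sum(
                1 for xi, ci in zip(x, labels)
                if (pol if xi > t else -pol) != ci
            ) / n
            best = min(best, err)
    return best
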