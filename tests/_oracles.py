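"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own formulas: the at-least-one
probability is computed by enumerating all 2^n joint Bernoulli outcomes, and
the ROC AUC by counting positive-negative pairs.
"""

from __future__ import annotations

import itertools
from typing import Sequence


def at_least_one_probability(ps: Sequence[float]) -> float:
    """P(>=1 success) among independent Bernoulli(p_i) by full enumeration."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(ps)):
        if not any(outcome):
            continue
        prob = 1.0
        for hit, p in zip(outcome, ps):
            prob *= p if hit else (1.0 - p)
        total += prob
    return total


def pair_counting_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: concordant pairs + half ties over all pos-neg pairs."""
    positives = [s for y, s in zip(labels, scores) if y == 1]
    negatives = [s for y, s in zip(labels, scores) if y == 0]
    if not positives or not negatives:
        raise ValueError("need both classes")
    wins = 0.0
    for sp in positives:
        for sn in negatives:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(positives) * len(negatives))
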