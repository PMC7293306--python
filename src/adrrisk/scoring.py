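"""Probabilistic ADR scoring and ranking.

Every score is the probability of "at least one" event among independent
Bernoulli trials, i.e. the complement of the Poisson-binomial mass at zero:

* frequency score of an ADR over a drug combination:
  ``1 - prod_i (1 - f_i)`` over the drugs listing that ADR with frequency f_i;
* severity score of an ADR: ``1 - (1 - Pr_hosp)(1 - Pr_mort)``, the chance of
  hospitalization or death given the ADR appears;
* per-ADR combined score: frequency x severity — the chance the ADR both
  appears and leads to a severe event;
* total score: ``1 - prod_j (1 - score_j)`` over ADRs whose severity score
  passes the clinical-relevance threshold (default 0.7, inclusive);
* SOC score: the same aggregation restricted to one System Organ Class, so
  that ``prod_SOC (1 - soc_score) == 1 - total_score`` (partition law).

Ranking sorts the passing ADRs by combined score, descending, ties broken
lexicographically by PT, truncated to ``top_k``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError

__all__ = [
    "SeverityPrediction",
    "ScoredADR",
    "RiskProfile",
    "ScoringConfig",
    "frequency_score",
    "severity_score",
    "combined_adr_score",
    "total_score",
    "soc_scores",
    "cumulative_outcome_risk",
    "rank_adrs",
]


def _check_probability(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0 or math.isnan(value):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


def _complement_product(probabilities: Iterable[float]) -> float:
    """prod (1 - p); factors multiplied in sorted order for stable accumulation."""
    product = 1.0
    for p in sorted(probabilities):
        product *= 1.0 - p
    return product


@dataclass(frozen=True)
class SeverityPrediction:
    """Hospitalization/mortality probabilities for one ADR and their combination."""

    pt_name: str
    pr_hosp: float
    pr_mort: float

    def __post_init__(self) -> None:
        _check_probability(self.pr_hosp, "pr_hosp")
        _check_probability(self.pr_mort, "pr_mort")

    @property
    def severity(self) -> float:
        return severity_score(self.pr_hosp, self.pr_mort)


@dataclass(frozen=True)
class ScoredADR:
    """One candidate ADR with its frequency, severity and combined scores."""

    pt_name: str
    soc_name: str
    frequency_score: float
    severity_score: float
    score: float
    rank: int | None = None

    @classmethod
    def build(
        cls, pt_name: str, soc_name: str, freq_score: float, sev_score: float
    ) -> "ScoredADR":
        return cls(
            pt_name,
            soc_name,
            _check_probability(freq_score, "frequency_score"),
            _check_probability(sev_score, "severity_score"),
            combined_adr_score(freq_score, sev_score),
        )


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds controlling aggregation and ranking.

    severity_threshold: minimum severity score (inclusive) for an ADR to count
        as clinically relevant; 0.7 per the scoring system's definition.
    top_k: length of the ranked ADR list.
    n_top_socs: number of SOC groupings reported in the risk profile.
    """

    severity_threshold: float = 0.7
    top_k: int = 20
    n_top_socs: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.severity_threshold <= 1.0:
            raise ValidationError(
                f"severity_threshold must lie in (0, 1], got {self.severity_threshold}"
            )
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {self.top_k}")
        if self.n_top_socs < 1:
            raise ValidationError(f"n_top_socs must be >= 1, got {self.n_top_socs}")


@dataclass(frozen=True)
class RiskProfile:
    """Per-patient output: aggregated risks, per-SOC scores, ranked ADR list."""

    total_score: float
    hospitalization_risk: float
    mortality_risk: float
    soc_scores: Mapping[str, float]
    ranked_adrs: tuple[ScoredADR, ...]

    def top_socs(self, n: int = 5) -> list[tuple[str, float]]:
        """The n highest-scoring SOCs, descending, ties broken by name."""
        ordered = sorted(self.soc_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ordered[:n]


def frequency_score(freqs: Sequence[float]) -> float:
    """Probability that at least one drug in the combination causes the ADR.

    ``1 - prod_i (1 - f_i)`` over the per-drug frequencies; an empty list
    (no drug lists the ADR) scores 0.
    """
    for f in freqs:
        _check_probability(f, "frequency")
    return 1.0 - _complement_product(freqs)


def severity_score(pr_hosp: float, pr_mort: float) -> float:
    """Probability of hospitalization or death, given the ADR appears."""
    _check_probability(pr_hosp, "pr_hosp")
    _check_probability(pr_mort, "pr_mort")
    return 1.0 - (1.0 - pr_hosp) * (1.0 - pr_mort)


def combined_adr_score(freq_score: float, sev_score: float) -> float:
    """Probability that the ADR both appears and leads to a severe event."""
    _check_probability(freq_score, "frequency_score")
    _check_probability(sev_score, "severity_score")
    return freq_score * sev_score


def _passing(scored: Iterable[ScoredADR], config: ScoringConfig) -> list[ScoredADR]:
    return [s for s in scored if s.severity_score >= config.severity_threshold]


def total_score(scored: Iterable[ScoredADR], config: ScoringConfig = ScoringConfig()) -> float:
    """Probability of at least one severe-ADR event among the passing ADRs."""
    return 1.0 - _complement_product(s.score for s in _passing(scored, config))


def soc_scores(
    scored: Sequence[ScoredADR], config: ScoringConfig = ScoringConfig()
) -> dict[str, float]:
    """The total-score aggregation restricted to each System Organ Class.

    Every SOC carried by an input ADR is a key; SOCs with no passing ADR map
    to 0.  The per-SOC complement products multiply back to 1 - total_score.
    """
    for s in scored:
        if not s.soc_name:
            raise ValidationError(f"ADR {s.pt_name!r} has no SOC annotation")
    by_soc: dict[str, list[float]] = {s.soc_name: [] for s in scored}
    for s in _passing(scored, config):
        by_soc[s.soc_name].append(s.score)
    return {
        soc: 1.0 - _complement_product(scores) for soc, scores in sorted(by_soc.items())
    }


def cumulative_outcome_risk(
    scored: Sequence[tuple[float, SeverityPrediction]],
    config: ScoringConfig = ScoringConfig(),
    outcome: str = "hospitalization",
) -> float:
    """Probability of at least one ADR appearing and causing the given outcome.

    ``1 - prod_j (1 - freq_j * pr_outcome_j)`` over the severity-passing ADRs;
    the outcome-specific analogue of the total score, hence never above it.
    """
    if outcome not in ("hospitalization", "mortality"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    terms = []
    for freq, prediction in scored:
        _check_probability(freq, "frequency_score")
        if prediction.severity >= config.severity_threshold:
            pr = prediction.pr_hosp if outcome == "hospitalization" else prediction.pr_mort
            terms.append(freq * pr)
    return 1.0 - _complement_product(terms)


def rank_adrs(
    scored: Iterable[ScoredADR], config: ScoringConfig = ScoringConfig()
) -> list[ScoredADR]:
    """Severity-passing ADRs sorted by combined score (desc, PT tie-break), top_k kept."""
    ordered = sorted(_passing(scored, config), key=lambda s: (-s.score, s.pt_name))
    return [
        dataclasses.replace(s, rank=i)
        for i, s in enumerate(ordered[: config.top_k], start=1)
    ]
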