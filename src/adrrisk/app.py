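"""End-to-end patient assessment.

Wires the knowledge base, the severity model and the scoring rules into one
call: for a patient (age, gender, drug list, comorbidities) compute every
candidate ADR's frequency and severity scores, then the Total Score, the
hospitalization/mortality risk stratification, the per-SOC scores and the
ranked top-k ADR list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .knowledge_base import KnowledgeBase, canonical_drug
from .reports import CANONICAL_PATHOLOGIES
from .scoring import (
    RiskProfile,
    ScoredADR,
    ScoringConfig,
    SeverityPrediction,
    cumulative_outcome_risk,
    frequency_score,
    rank_adrs,
    soc_scores,
    total_score,
)
from .severity_model import SeverityModel, encode_instance

__all__ = ["PatientQuery", "assess_patient", "render_profile", "profile_from_json"]


@dataclass(frozen=True)
class PatientQuery:
    """The assessment inputs: age, gender, drug combination, comorbidities."""

    age: int
    gender: str
    drugs: frozenset[str]
    pathologies: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.gender not in ("male", "female"):
            raise ValidationError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if not self.drugs:
            raise ValidationError("at least one drug is required for an assessment")
        extra = set(self.pathologies) - set(CANONICAL_PATHOLOGIES)
        if extra:
            raise ValidationError(
                f"unknown pathology flag(s): {sorted(extra)}; allowed: {CANONICAL_PATHOLOGIES}"
            )


def assess_patient(
    query: PatientQuery,
    kb: KnowledgeBase,
    model: SeverityModel,
    config: ScoringConfig = ScoringConfig(),
) -> RiskProfile:
    """Compute the full risk profile for one patient.

    Pipeline: candidate ADR profile over the queried drugs; per-ADR frequency
    score (chance any drug causes it); per-ADR hospitalization/mortality
    probabilities from the severity model, querying one ADR at a time;
    combined scores; then the aggregate Total Score, per-SOC scores,
    cumulative outcome risks and the ranked list.  Deterministic for a fixed
    trained model.
    """
    candidates = kb.candidate_adr_profile(query.drugs)  # warns on unknown drugs
    resolvable = {canonical_drug(d) for d in query.drugs} & set(kb.drugs)
    if not resolvable:
        raise ValidationError(
            f"none of the queried drugs are in the knowledge base: {sorted(query.drugs)}"
        )
    if not candidates:
        return RiskProfile(0.0, 0.0, 0.0, {}, ())

    X = np.stack(
        [
            encode_instance(
                query.age, query.gender, resolvable, query.pathologies,
                {c.pt_name}, model.vocabulary,
            )
            for c in candidates
        ]
    )
    pr_hosp = model.predict_proba_matrix(X, "hospitalization")
    pr_mort = model.predict_proba_matrix(X, "mortality")

    scored: list[ScoredADR] = []
    with_predictions: list[tuple[float, SeverityPrediction]] = []
    for candidate, ph, pm in zip(candidates, pr_hosp, pr_mort):
        prediction = SeverityPrediction(candidate.pt_name, float(ph), float(pm))
        freq = frequency_score(candidate.frequencies)
        scored.append(
            ScoredADR.build(candidate.pt_name, candidate.soc_name, freq, prediction.severity)
        )
        with_predictions.append((freq, prediction))

    return RiskProfile(
        total_score=total_score(scored, config),
        hospitalization_risk=cumulative_outcome_risk(with_predictions, config, "hospitalization"),
        mortality_risk=cumulative_outcome_risk(with_predictions, config, "mortality"),
        soc_scores=soc_scores(scored, config),
        ranked_adrs=tuple(rank_adrs(scored, config)),
    )


def _profile_to_dict(profile: RiskProfile) -> dict:
    return {
        "total_score": profile.total_score,
        "hospitalization_risk": profile.hospitalization_risk,
        "mortality_risk": profile.mortality_risk,
        "soc_scores": dict(profile.soc_scores),
        "ranked_adrs": [
            {
                "rank": s.rank,
                "pt": s.pt_name,
                "soc": s.soc_name,
                "frequency_score": s.frequency_score,
                "severity_score": s.severity_score,
                "score": s.score,
            }
            for s in profile.ranked_adrs
        ],
    }


def profile_from_json(text: str) -> RiskProfile:
    data = json.loads(text)
    return RiskProfile(
        total_score=data["total_score"],
        hospitalization_risk=data["hospitalization_risk"],
        mortality_risk=data["mortality_risk"],
        soc_scores=data["soc_scores"],
        ranked_adrs=tuple(
            ScoredADR(
                pt_name=s["pt"],
                soc_name=s["soc"],
                frequency_score=s["frequency_score"],
                severity_score=s["severity_score"],
                score=s["score"],
                rank=s["rank"],
            )
            for s in data["ranked_adrs"]
        ),
    )


def render_profile(
    profile: RiskProfile, format: str = "text", n_top_socs: int = 5
) -> str:
    """Serialize a risk profile as json (lossless), tsv, or a readable text report."""
    if format == "json":
        return json.dumps(_profile_to_dict(profile), indent=2, sort_keys=True)
    if format == "tsv":
        lines = ["rank\tpt\tsoc\tfrequency_score\tseverity_score\tscore"]
        for s in profile.ranked_adrs:
            lines.append(
                f"{s.rank}\t{s.pt_name}\t{s.soc_name}\t{s.frequency_score!r}"
                f"\t{s.severity_score!r}\t{s.score!r}"
            )
        return "\n".join(lines) + "\n"
    if format == "text":
        lines = [
            f"Total Score:          {profile.total_score * 100:.2f}%",
            f"Hospitalization Risk: {profile.hospitalization_risk * 100:.2f}%",
            f"Mortality Risk:       {profile.mortality_risk * 100:.2f}%",
            "",
            f"Top {n_top_socs} System Organ Classes:",
        ]
        for soc, score in profile.top_socs(n_top_socs):
            lines.append(f"  {soc}: {score * 100:.2f}%")
        lines += ["", "Ranked ADRs (severity-passing, by combined score):"]
        if not profile.ranked_adrs:
            lines.append("  (none above the severity threshold)")
        for s in profile.ranked_adrs:
            lines.append(f"  {s.rank:>3}. {s.pt_name} [{s.soc_name}] {s.score * 100:.2f}%")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown format {format!r}; expected json, tsv or text")
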