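"""Synthetic knowledge bases and spontaneous-report corpora.

Real side-effect frequency tables and spontaneous-report systems cannot ship
with the package, so this module generates both from a fully known generative
model.  The point is testability: because outcome labels are drawn from a
logistic model whose coefficients we hold, :func:`true_outcome_probability`
is an exact Bayes oracle — a trained severity classifier can be judged
against the best score any classifier could achieve on the same corpus.

Generation of one report consumes the shared random stream in a fixed,
documented order: age, gender, drug subset, pathology flags, per-(drug, ADR)
Bernoulli fires, then the two outcome draws.  Reports whose ADR set comes out
empty are rejected and redrawn in full, so every stored report carries at
least one ADR; this conditions the corpus slightly but keeps each per-drug
frequency interpretable as P(ADR | drug taken) before conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ValidationError
from .knowledge_base import DrugADRFrequency, KnowledgeBase
from .reports import CANONICAL_PATHOLOGIES, ReportRecord

__all__ = [
    "OutcomeModel",
    "GenerativeSpec",
    "generate_knowledge_base",
    "generate_report_corpus",
    "true_outcome_probability",
    "moderate_generative_spec",
    "save_generative_spec",
    "load_generative_spec",
]

OUTCOMES = ("hospitalization", "mortality")

#: Age is divided by this before entering the linear predictor, matching the
#: feature encoding used by the severity classifier.
AGE_SCALE = 100.0


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for one outcome: P = sigmoid(linear predictor)."""

    intercept: float
    age: float  # per scaled-age unit (age / 100)
    gender: float  # added for male patients
    drug: Mapping[str, float] = field(default_factory=dict)
    pathology: Mapping[str, float] = field(default_factory=dict)
    adr: Mapping[str, float] = field(default_factory=dict)

    def linear_predictor(self, record: ReportRecord) -> float:
        lp = self.intercept
        lp += self.age * (record.age / AGE_SCALE)
        lp += self.gender * (1.0 if record.gender == "male" else 0.0)
        for name in record.drugs:
            if name not in self.drug:
                raise ValidationError(f"drug {name!r} has no generative coefficient")
            lp += self.drug[name]
        for name in record.pathologies:
            if name not in self.pathology:
                raise ValidationError(f"pathology {name!r} has no generative coefficient")
            lp += self.pathology[name]
        for name in record.adrs:
            if name not in self.adr:
                raise ValidationError(f"ADR {name!r} has no generative coefficient")
            lp += self.adr[name]
        return lp


@dataclass(frozen=True)
class GenerativeSpec:
    """Everything needed to sample a corpus: demographics + two outcome models."""

    hospitalization: OutcomeModel
    mortality: OutcomeModel
    age_mean: float = 60.0
    age_sd: float = 15.0
    age_min: int = 18
    age_max: int = 100
    p_male: float = 0.5
    drugs_min: int = 1
    drugs_max: int = 8
    pathology_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.1 for p in CANONICAL_PATHOLOGIES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValidationError("age bounds out of order")
        if not 0.0 <= self.p_male <= 1.0:
            raise ValidationError(f"p_male must lie in [0, 1], got {self.p_male}")
        if not 1 <= self.drugs_min <= self.drugs_max:
            raise ValidationError("drugs-per-report range invalid")
        for name, p in self.pathology_prevalence.items():
            if name not in CANONICAL_PATHOLOGIES:
                raise ValidationError(f"unknown pathology {name!r} in prevalence map")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence of {name!r} outside [0, 1]")

    def outcome_model(self, outcome: str) -> OutcomeModel:
        if outcome == "hospitalization":
            return self.hospitalization
        if outcome == "mortality":
            return self.mortality
        raise ValidationError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def _sigmoid(x: float) -> float:
    # guard against overflow for saturated intercepts
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def true_outcome_probability(
    spec: GenerativeSpec, record: ReportRecord, outcome: str
) -> float:
    """Exact P(outcome | record) under the generative model (Bayes oracle)."""
    return _sigmoid(spec.outcome_model(outcome).linear_predictor(record))


def generate_knowledge_base(
    n_drugs: int,
    n_adrs: int,
    n_socs: int,
    adrs_per_drug: tuple[int, int] = (2, 8),
    frequency_law: tuple[float, float] = (0.9, 9.0),
    seed: int = 0,
) -> KnowledgeBase:
    """Sample a drug -> ADR frequency table with a PT -> SOC partition.

    Each drug lists a uniform-random number of ADRs in ``adrs_per_drug``;
    frequencies are Beta(``frequency_law``) draws clipped into (0, 1] — the
    default Beta(0.9, 9) has mean ~0.09, echoing the low typical label
    frequencies of real side-effect tables.  Every ADR gets exactly one SOC
    and every SOC at least one ADR.
    """
    if n_drugs < 1 or n_adrs < 1 or n_socs < 1:
        raise ValidationError("n_drugs, n_adrs and n_socs must all be >= 1")
    if n_socs > n_adrs:
        raise ValidationError(f"n_socs ({n_socs}) cannot exceed n_adrs ({n_adrs})")
    lo, hi = adrs_per_drug
    if not 1 <= lo <= hi <= n_adrs:
        raise ValidationError(
            f"adrs_per_drug range {adrs_per_drug} must lie within [1, {n_adrs}]"
        )
    alpha, beta = frequency_law
    if alpha <= 0 or beta <= 0:
        raise ValidationError("frequency_law Beta parameters must be positive")

    rng = np.random.default_rng(seed)
    drugs = [f"drug{i:03d}" for i in range(n_drugs)]
    pts = [f"Adr {j:03d}" for j in range(n_adrs)]
    socs = [f"Soc {k:02d}" for k in range(n_socs)]

    # first n_socs PTs pin one ADR per SOC; the rest are assigned uniformly
    soc_map = {pts[k]: socs[k] for k in range(n_socs)}
    for j in range(n_socs, n_adrs):
        soc_map[pts[j]] = socs[rng.integers(0, n_socs)]

    records: list[DrugADRFrequency] = []
    for drug in drugs:
        count = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(n_adrs, size=count, replace=False)
        freqs = np.clip(rng.beta(alpha, beta, size=count), 1e-6, 1.0)
        for j, f in zip(sorted(chosen.tolist()), freqs):
            records.append(DrugADRFrequency(drug, pts[j], float(f)))
    return KnowledgeBase(records, soc_map)


def _draw_truncated_age(rng: np.random.Generator, spec: GenerativeSpec) -> int:
    """Rejection-sample a truncated normal age, rounded to whole years."""
    while True:
        age = rng.normal(spec.age_mean, spec.age_sd)
        if spec.age_min <= age <= spec.age_max:
            return int(round(age))


def _draw_report(
    rng: np.random.Generator, kb: KnowledgeBase, spec: GenerativeSpec
) -> ReportRecord | None:
    """One attempt at a report; None when no candidate ADR fires."""
    age = _draw_truncated_age(rng, spec)
    gender = "male" if rng.random() < spec.p_male else "female"
    n_drugs = int(rng.integers(spec.drugs_min, min(spec.drugs_max, len(kb.drugs)) + 1))
    drugs = sorted(rng.choice(kb.drugs, size=n_drugs, replace=False).tolist())
    pathologies = frozenset(
        p
        for p in CANONICAL_PATHOLOGIES
        if rng.random() < spec.pathology_prevalence.get(p, 0.0)
    )
    fired: set[str] = set()
    for profile in kb.candidate_adr_profile(drugs):
        for _, freq in profile.contributing_frequencies:
            if rng.random() < freq:
                fired.add(profile.pt_name)
    if not fired:
        return None
    partial = ReportRecord(
        age=age,
        gender=gender,
        drugs=frozenset(drugs),
        pathologies=pathologies,
        adrs=frozenset(fired),
        hospitalized=False,
        fatal_or_life_threat=False,
    )
    p_hosp = true_outcome_probability(spec, partial, "hospitalization")
    p_mort = true_outcome_probability(spec, partial, "mortality")
    return ReportRecord(
        age=age,
        gender=gender,
        drugs=partial.drugs,
        pathologies=pathologies,
        adrs=partial.adrs,
        hospitalized=bool(rng.random() < p_hosp),
        fatal_or_life_threat=bool(rng.random() < p_mort),
    )


def generate_report_corpus(
    kb: KnowledgeBase, spec: GenerativeSpec, n_reports: int
) -> list[ReportRecord]:
    """Sample ``n_reports`` reports; a pure function of (kb, spec, n_reports)."""
    if n_reports <= 0:
        raise ValidationError(f"n_reports must be positive, got {n_reports}")
    rng = np.random.default_rng(spec.seed)
    records: list[ReportRecord] = []
    attempts_left = 1000 * n_reports
    while len(records) < n_reports:
        if attempts_left <= 0:
            raise ValidationError(
                "rejection sampling failed: knowledge-base frequencies are too "
                "small for reports to carry any ADR"
            )
        attempts_left -= 1
        report = _draw_report(rng, kb, spec)
        if report is not None:
            records.append(report)
    return records


def moderate_generative_spec(kb: KnowledgeBase, seed: int = 0) -> GenerativeSpec:
    """A GenerativeSpec with moderate, reproducible effect sizes for a given KB.

    Per-entity log-odds coefficients are drawn once from centred normals
    (drugs sd 0.6, ADRs sd 0.8, pathologies sd 0.5); age enters at +2 (hosp)
    and +3 (mort) per scaled-age unit and intercepts are set for roughly 45%
    hospitalization and 20% mortality base rates — the mild-imbalance regime
    typical of spontaneous-report outcome flags.
    """
    rng = np.random.default_rng(seed)

    def draw(names: list[str], sd: float) -> dict[str, float]:
        return {name: float(v) for name, v in zip(names, rng.normal(0.0, sd, len(names)))}

    hosp = OutcomeModel(
        intercept=-1.5,
        age=2.0,
        gender=0.3,
        drug=draw(kb.drugs, 0.6),
        pathology=draw(list(CANONICAL_PATHOLOGIES), 0.5),
        adr=draw(kb.pts, 0.8),
    )
    mort = OutcomeModel(
        intercept=-3.5,
        age=3.0,
        gender=0.5,
        drug=draw(kb.drugs, 0.6),
        pathology=draw(list(CANONICAL_PATHOLOGIES), 0.5),
        adr=draw(kb.pts, 0.8),
    )
    return GenerativeSpec(hospitalization=hosp, mortality=mort, seed=seed)


def save_generative_spec(spec: GenerativeSpec, path: str | Path) -> None:
    """Serialize the spec as YAML for provenance alongside a corpus."""
    payload = asdict(spec)
    payload["hospitalization"] = asdict(spec.hospitalization)
    payload["mortality"] = asdict(spec.mortality)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_generative_spec(path: str | Path) -> GenerativeSpec:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    hosp = OutcomeModel(**payload.pop("hospitalization"))
    mort = OutcomeModel(**payload.pop("mortality"))
    return GenerativeSpec(hospitalization=hosp, mortality=mort, **payload)
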