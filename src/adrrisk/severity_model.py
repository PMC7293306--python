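"""Severity prediction: an ensemble of logistic-activation MLP classifiers.

Two ensembles are trained on spontaneous-report instances — one for the
hospitalization outcome, one for death/life-threat — and their averaged
class-1 probabilities feed the severity score.  A training instance is one
report: scaled age, a gender indicator, and multi-hot indicators for the
drugs, the six comorbidities and the observed ADR set.  At scoring time the
query is encoded with a single ADR bit, asking "would THIS ADR, for THIS
patient on THIS therapy, end in hospitalization / death?".

Each ensemble holds five MLPs sharing one hyperparameter set (40 logistic
hidden units, at most 500 iterations, loss tolerance 0.1) and differing only
by random seed; the ensemble probability is the unweighted mean of the
members'.  The mortality training set is rebalanced by random minority
oversampling before fitting; the hospitalization set is used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier

from .exceptions import ValidationError
from .knowledge_base import KnowledgeBase, canonical_drug, canonical_pt
from .reports import CANONICAL_PATHOLOGIES, ReportRecord

__all__ = [
    "FeatureVocabulary",
    "EnsembleConfig",
    "SeverityModel",
    "build_vocabulary",
    "encode_instance",
    "build_training_matrices",
    "oversample_minority",
    "train_severity_ensemble",
    "train_severity_model",
]

AGE_SCALE = 100.0


@dataclass(frozen=True)
class FeatureVocabulary:
    """Stable, lexicographic orderings of the indicator features.

    Layout of an encoded vector: [age/100, gender(male=1), drug indicators,
    pathology indicators, ADR indicators].
    """

    drugs: tuple[str, ...]
    pathologies: tuple[str, ...] = CANONICAL_PATHOLOGIES
    adrs: tuple[str, ...] = ()
    age_scale: float = AGE_SCALE

    def __post_init__(self) -> None:
        for name, values in (("drugs", self.drugs), ("pathologies", self.pathologies), ("adrs", self.adrs)):
            if len(set(values)) != len(values):
                raise ValidationError(f"duplicate entries in {name} vocabulary")

    @property
    def n_features(self) -> int:
        return 2 + len(self.drugs) + len(self.pathologies) + len(self.adrs)

    def _index(self, kind: str) -> dict[str, int]:
        offset = {"drug": 2, "pathology": 2 + len(self.drugs), "adr": 2 + len(self.drugs) + len(self.pathologies)}[kind]
        names = {"drug": self.drugs, "pathology": self.pathologies, "adr": self.adrs}[kind]
        return {name: offset + i for i, name in enumerate(names)}


def build_vocabulary(records: Sequence[ReportRecord], kb: KnowledgeBase) -> FeatureVocabulary:
    """Vocabulary covering every KB drug and PT plus the six pathologies.

    Fails if the corpus mentions an entity the knowledge base does not carry,
    since such a report could not be encoded consistently at scoring time.
    """
    if not records:
        raise ValidationError("cannot build a vocabulary from an empty corpus")
    drugs = tuple(kb.drugs)
    adrs = tuple(kb.pts)
    drug_set, adr_set = set(drugs), set(adrs)
    for record in records:
        for d in record.drugs:
            if d not in drug_set:
                raise ValidationError(f"corpus drug {d!r} absent from knowledge base")
        for a in record.adrs:
            if a not in adr_set:
                raise ValidationError(f"corpus ADR {a!r} absent from knowledge base")
    return FeatureVocabulary(drugs=drugs, adrs=adrs)


def encode_instance(
    age: float,
    gender: str,
    drugs: Iterable[str],
    pathologies: Iterable[str],
    adr_set: Iterable[str],
    vocab: FeatureVocabulary,
) -> np.ndarray:
    """Encode one (patient, drug combination, ADR set) instance as a float vector."""
    if age < 0:
        raise ValidationError(f"age must be >= 0, got {age}")
    if gender not in ("male", "female"):
        raise ValidationError(f"gender must be 'male' or 'female', got {gender!r}")
    x = np.zeros(vocab.n_features)
    x[0] = age / vocab.age_scale
    x[1] = 1.0 if gender == "male" else 0.0
    for kind, values in (("drug", drugs), ("pathology", pathologies), ("adr", adr_set)):
        index = vocab._index(kind)
        for name in values:
            key = canonical_drug(name) if kind == "drug" else (name if kind == "pathology" else canonical_pt(name))
            if key not in index:
                raise ValidationError(f"unknown {kind} {name!r} (not in vocabulary)")
            x[index[key]] = 1.0
    return x


def build_training_matrices(
    records: Sequence[ReportRecord], vocab: FeatureVocabulary
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One row per report (full ADR set multi-hot) with both outcome labels."""
    X = np.empty((len(records), vocab.n_features))
    y_hosp = np.empty(len(records), dtype=int)
    y_mort = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        X[i] = encode_instance(r.age, r.gender, r.drugs, r.pathologies, r.adrs, vocab)
        y_hosp[i] = int(r.hospitalized)
        y_mort[i] = int(r.fatal_or_life_threat)
    return X, y_hosp, y_mort


def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    target_counts: Mapping[int, int],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random oversampling with replacement up to exact per-class targets.

    Appended rows are drawn (with replacement) from the rows of their own
    class, so the output support equals the input support; original rows are
    kept first, appended rows follow in class order.  A target below the
    observed count is an error — this operation never undersamples.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y row counts differ")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValidationError("both classes must be present before oversampling")
    rng = np.random.default_rng(seed)
    extra_indices: list[np.ndarray] = []
    for cls in classes:
        observed = int(np.sum(y == cls))
        target = int(target_counts.get(cls, observed))
        if target < observed:
            raise ValidationError(
                f"target count {target} for class {cls} is below the observed {observed}"
            )
        if target > observed:
            pool = np.flatnonzero(y == cls)
            extra_indices.append(rng.choice(pool, size=target - observed, replace=True))
    if not extra_indices:
        return X.copy(), y.copy()
    extra = np.concatenate(extra_indices)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters shared by the five ensemble members.

    ``oversample_target`` applies to the mortality ensemble only: "balance"
    raises every class to the majority count, a {class: count} mapping sets
    exact targets, None disables resampling.
    """

    n_members: int = 5
    hidden_layer_size: int = 40
    max_iterations: int = 500
    tolerance: float = 0.1
    activation: str = "logistic"
    member_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    oversample_target: str | Mapping[int, int] | None = "balance"
    classification_threshold: float = 0.5
    bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        if self.hidden_layer_size < 1:
            raise ValidationError("hidden_layer_size must be >= 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValidationError("classification_threshold must lie in (0, 1)")
        if len(self.member_seeds) != self.n_members:
            raise ValidationError(
                f"need {self.n_members} member seeds, got {len(self.member_seeds)}"
            )

    def with_seed(self, seed: int) -> "EnsembleConfig":
        """Derive member seeds deterministically from one base seed (< 2^31)."""
        seeds = tuple(int(s) for s in (seed + np.arange(self.n_members)) % (2**31))
        return replace(self, member_seeds=seeds)


def train_severity_ensemble(
    X: np.ndarray, y: np.ndarray, config: EnsembleConfig = EnsembleConfig()
) -> list[MLPClassifier]:
    """Fit the ensemble members; deterministic given the member seeds."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    members = []
    for seed in config.member_seeds:
        Xm, ym = X, y
        if config.bootstrap:
            idx = np.random.default_rng(seed).integers(0, len(y), size=len(y))
            Xm, ym = X[idx], y[idx]
            if len(np.unique(ym)) < 2:  # tiny-set bootstrap may drop a class
                Xm, ym = X, y
        member = MLPClassifier(
            hidden_layer_sizes=(config.hidden_layer_size,),
            activation=config.activation,
            max_iter=config.max_iterations,
            tol=config.tolerance,
            random_state=seed,
        )
        member.fit(Xm, ym)
        members.append(member)
    return members


@dataclass
class SeverityModel:
    """Trained hospitalization + mortality ensembles over one vocabulary."""

    hospitalization: list[MLPClassifier]
    mortality: list[MLPClassifier]
    vocabulary: FeatureVocabulary
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    def _members(self, outcome: str) -> list[MLPClassifier]:
        if outcome == "hospitalization":
            return self.hospitalization
        if outcome == "mortality":
            return self.mortality
        raise ValidationError(f"unknown outcome {outcome!r}")

    def predict_proba_matrix(self, X: np.ndarray, outcome: str) -> np.ndarray:
        """Ensemble (mean-of-members) class-1 probabilities for a feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.vocabulary.n_features:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match vocabulary "
                f"({self.vocabulary.n_features})"
            )
        members = self._members(outcome)
        stacked = np.stack([m.predict_proba(X)[:, 1] for m in members])
        return np.clip(stacked.mean(axis=0), 0.0, 1.0)

    def predict_outcome_probability(self, x: np.ndarray, outcome: str) -> float:
        return float(self.predict_proba_matrix(np.asarray(x).reshape(1, -1), outcome)[0])

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "SeverityModel":
        model = joblib.load(path)
        if not isinstance(model, SeverityModel):
            raise ValidationError(f"{path} does not contain a SeverityModel")
        return model


def _resolve_targets(
    y: np.ndarray, target: str | Mapping[int, int] | None
) -> Mapping[int, int] | None:
    if target is None:
        return None
    if target == "balance":
        counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
        top = max(counts.values())
        return {c: top for c in counts}
    if isinstance(target, Mapping):
        return target
    raise ValidationError(f"unsupported oversample_target {target!r}")


def train_severity_model(
    records: Sequence[ReportRecord],
    kb: KnowledgeBase,
    config: EnsembleConfig = EnsembleConfig(),
    oversample_seed: int = 0,
) -> SeverityModel:
    """End-to-end training: vocabulary, matrices, mortality oversampling, both ensembles."""
    vocab = build_vocabulary(records, kb)
    X, y_hosp, y_mort = build_training_matrices(records, vocab)
    targets = _resolve_targets(y_mort, config.oversample_target)
    if targets is not None:
        X_mort, y_mort_fit = oversample_minority(X, y_mort, targets, seed=oversample_seed)
    else:
        X_mort, y_mort_fit = X, y_mort
    return SeverityModel(
        hospitalization=train_severity_ensemble(X, y_hosp, config),
        mortality=train_severity_ensemble(X_mort, y_mort_fit, config),
        vocabulary=vocab,
        config=config,
    )
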