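from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from adrrisk.knowledge_base import DrugADRFrequency, KnowledgeBase
from adrrisk.severity_model import EnsembleConfig, FeatureVocabulary
from adrrisk.synthetic_data import (
    generate_knowledge_base,
    generate_report_corpus,
    moderate_generative_spec,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def three_row_kb() -> KnowledgeBase:
    """The minimal worked-example knowledge base: two drugs, two ADRs."""
    records = [
        DrugADRFrequency("druga", "Nausea", 0.10),
        DrugADRFrequency("druga", "Rash", 0.02),
        DrugADRFrequency("drugb", "Nausea", 0.25),
    ]
    soc_map = {"Nausea": "Gastrointestinal disorders", "Rash": "Skin disorders"}
    return KnowledgeBase(records, soc_map)


@pytest.fixture
def three_row_vocab(three_row_kb) -> FeatureVocabulary:
    return FeatureVocabulary(
        drugs=tuple(three_row_kb.drugs), adrs=tuple(three_row_kb.pts)
    )


class StubSeverityModel:
    """Severity model returning constant probabilities, for closed-form pipelines."""

    def __init__(self, vocabulary: FeatureVocabulary, pr_hosp: float, pr_mort: float):
        self.vocabulary = vocabulary
        self._pr = {"hospitalization": pr_hosp, "mortality": pr_mort}

    def predict_proba_matrix(self, X, outcome):
        X = np.atleast_2d(X)
        return np.full(X.shape[0], self._pr[outcome])

    def predict_outcome_probability(self, x, outcome):
        return self._pr[outcome]


@pytest.fixture
def stub_model_factory():
    return StubSeverityModel


@pytest.fixture(scope="session")
def small_kb() -> KnowledgeBase:
    return generate_knowledge_base(n_drugs=12, n_adrs=30, n_socs=4, seed=5)


@pytest.fixture(scope="session")
def small_spec(small_kb):
    return moderate_generative_spec(small_kb, seed=5)


@pytest.fixture(scope="session")
def small_corpus(small_kb, small_spec):
    return generate_report_corpus(small_kb, small_spec, 1500)


@pytest.fixture(scope="session")
def small_model(small_kb, small_corpus):
    from adrrisk.severity_model import train_severity_model

    return train_severity_model(small_corpus, small_kb, EnsembleConfig(), oversample_seed=5)
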