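from __future__ import annotations

import numpy as np
import pytest

from adrrisk.exceptions import ValidationError
from adrrisk.reports import CANONICAL_PATHOLOGIES, ReportRecord
from adrrisk.severity_model import (
    EnsembleConfig,
    FeatureVocabulary,
    SeverityModel,
    build_training_matrices,
    build_vocabulary,
    encode_instance,
    oversample_minority,
    train_severity_ensemble,
)


class TestVocabulary:
    def test_covers_kb_and_canonical_pathologies(self, small_corpus, small_kb):
        vocab = build_vocabulary(small_corpus, small_kb)
        assert vocab.drugs == tuple(small_kb.drugs)
        assert vocab.adrs == tuple(small_kb.pts)
        assert vocab.pathologies == CANONICAL_PATHOLOGIES
        assert vocab.n_features == 2 + len(vocab.drugs) + 6 + len(vocab.adrs)

    def test_ordering_is_deterministic(self, small_corpus, small_kb):
        assert build_vocabulary(small_corpus, small_kb) == build_vocabulary(
            small_corpus, small_kb
        )

    def test_empty_corpus_rejected(self, small_kb):
        with pytest.raises(ValidationError):
            build_vocabulary([], small_kb)

    def test_corpus_drug_missing_from_kb_rejected(self, small_kb, small_corpus):
        rogue = ReportRecord(
            50, "male", frozenset({"rogue-drug"}), frozenset(),
            frozenset({small_kb.pts[0]}), False, False,
        )
        with pytest.raises(ValidationError, match="rogue-drug"):
            build_vocabulary(list(small_corpus[:5]) + [rogue], small_kb)


class TestEncodeInstance:
    def test_worked_example_bits(self, three_row_vocab):
        x = encode_instance(
            85, "male", {"druga"}, {"Cardiac failure"}, {"Nausea"}, three_row_vocab
        )
        # layout: [age, gender, druga, drugb, 6 pathologies, Nausea, Rash]
        assert x[0] == pytest.approx(0.85)
        assert x[1] == 1.0
        assert x[2] == 1.0 and x[3] == 0.0
        assert x[4] == 1.0 and x[5:10].sum() == 0.0  # Cardiac failure is first
        assert x[10] == 1.0 and x[11] == 0.0
        assert x.sum() == pytest.approx(0.85 + 4.0)

    def test_all_zero_except_adr_bit(self, three_row_vocab):
        x = encode_instance(0, "female", set(), set(), {"Nausea"}, three_row_vocab)
        assert x[10] == 1.0
        assert x.sum() == 1.0

    def test_unknown_entities_rejected(self, three_row_vocab):
        with pytest.raises(ValidationError):
            encode_instance(50, "male", {"druga"}, set(), {"Septic shock"}, three_row_vocab)
        with pytest.raises(ValidationError):
            encode_instance(50, "male", {"drugz"}, set(), {"Nausea"}, three_row_vocab)
        with pytest.raises(ValidationError):
            encode_instance(50, "male", {"druga"}, {"Gout"}, {"Nausea"}, three_row_vocab)


class TestTrainingMatrices:
    def test_one_row_per_report_with_labels(self, small_corpus, small_kb):
        vocab = build_vocabulary(small_corpus, small_kb)
        records = list(small_corpus[:100])
        X, y_hosp, y_mort = build_training_matrices(records, vocab)
        assert X.shape == (100, vocab.n_features)
        assert y_hosp.tolist() == [int(r.hospitalized) for r in records]
        assert y_mort.tolist() == [int(r.fatal_or_life_threat) for r in records]

    def test_multi_adr_report_sets_that_many_bits(self, small_corpus, small_kb):
        vocab = build_vocabulary(small_corpus, small_kb)
        adr_offset = 2 + len(vocab.drugs) + len(vocab.pathologies)
        X, _, _ = build_training_matrices(list(small_corpus), vocab)
        for row, record in zip(X, small_corpus):
            assert row[adr_offset:].sum() == len(record.adrs)

    def test_encoding_is_invertible(self, small_corpus, small_kb):
        """Decoding the indicator blocks recovers each report's entity sets."""
        vocab = build_vocabulary(small_corpus, small_kb)
        d, p = len(vocab.drugs), len(vocab.pathologies)
        X, _, _ = build_training_matrices(list(small_corpus[:50]), vocab)
        for row, record in zip(X, small_corpus):
            drugs = {vocab.drugs[i] for i in np.flatnonzero(row[2 : 2 + d])}
            paths = {vocab.pathologies[i] for i in np.flatnonzero(row[2 + d : 2 + d + p])}
            adrs = {vocab.adrs[i] for i in np.flatnonzero(row[2 + d + p :])}
            assert drugs == set(record.drugs)
            assert paths == set(record.pathologies)
            assert adrs == set(record.adrs)
            assert row[0] == pytest.approx(record.age / 100)


class TestOversampling:
    @staticmethod
    def _toy():
        X = np.arange(20.0).reshape(10, 2)
        y = np.array([0] * 8 + [1] * 2)
        return X, y

    def test_counts_hit_exact_targets(self):
        X, y = self._toy()
        X2, y2 = oversample_minority(X, y, {0: 8, 1: 8}, seed=0)
        assert len(y2) == 16
        assert int((y2 == 0).sum()) == 8 and int((y2 == 1).sum()) == 8

    def test_added_rows_duplicate_minority_rows(self):
        X, y = self._toy()
        X2, y2 = oversample_minority(X, y, {0: 8, 1: 8}, seed=0)
        minority_rows = {tuple(r) for r in X[y == 1]}
        assert all(tuple(r) in minority_rows for r in X2[10:])

    def test_targets_equal_observed_is_identity(self):
        X, y = self._toy()
        X2, y2 = oversample_minority(X, y, {0: 8, 1: 2}, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_target_below_observed_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValidationError):
            oversample_minority(X, y, {0: 4, 1: 8}, seed=0)

    def test_deterministic_given_seed(self):
        X, y = self._toy()
        a = oversample_minority(X, y, {0: 12, 1: 12}, seed=3)
        b = oversample_minority(X, y, {0: 12, 1: 12}, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            oversample_minority(X, np.zeros(4, dtype=int), {0: 8}, seed=0)


def _separable_toy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-3.0, 0.3, size=(n // 2, 2))
    X1 = rng.normal(3.0, 0.3, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestEnsembleTraining:
    def test_members_fit_separable_data_perfectly(self):
        X, y = _separable_toy()
        config = EnsembleConfig(tolerance=1e-4, max_iterations=2000)
        members = train_severity_ensemble(X, y, config)
        assert len(members) == 5
        for member in members:
            assert (member.predict(X) == y).all()

    def test_training_is_deterministic(self):
        X, y = _separable_toy()
        config = EnsembleConfig()
        a = train_severity_ensemble(X, y, config)
        b = train_severity_ensemble(X, y, config)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.predict_proba(X), mb.predict_proba(X))

    def test_single_class_labels_rejected(self):
        X, _ = _separable_toy()
        with pytest.raises(ValidationError):
            train_severity_ensemble(X, np.ones(len(X), dtype=int), EnsembleConfig())

    def test_config_contracts(self):
        with pytest.raises(ValidationError):
            EnsembleConfig(tolerance=0.0)
        with pytest.raises(ValidationError):
            EnsembleConfig(n_members=0, member_seeds=())
        with pytest.raises(ValidationError):
            EnsembleConfig(member_seeds=(1, 2, 3))
        seeds = EnsembleConfig().with_seed(123).member_seeds
        assert seeds == (123, 124, 125, 126, 127)


class _ConstantMember:
    """Stands in for a fitted MLP returning one fixed class-1 probability."""

    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


class TestEnsemblePrediction:
    @staticmethod
    def _stub_model(probs, vocab):
        members = [_ConstantMember(p) for p in probs]
        return SeverityModel(
            hospitalization=members, mortality=members, vocabulary=vocab
        )

    def test_mean_of_identical_members(self, three_row_vocab):
        model = self._stub_model([0.2] * 5, three_row_vocab)
        x = np.zeros(three_row_vocab.n_features)
        assert model.predict_outcome_probability(x, "hospitalization") == pytest.approx(0.2)

    def test_mean_of_spread_members(self, three_row_vocab):
        model = self._stub_model([0.0, 0.25, 0.5, 0.75, 1.0], three_row_vocab)
        x = np.zeros(three_row_vocab.n_features)
        assert model.predict_outcome_probability(x, "mortality") == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self, three_row_vocab):
        model = self._stub_model([0.5] * 5, three_row_vocab)
        with pytest.raises(ValidationError):
            model.predict_proba_matrix(np.zeros((1, 3)), "hospitalization")

    def test_ensemble_mean_within_member_range(self, small_model, small_corpus, small_kb):
        X, _, _ = build_training_matrices(list(small_corpus[:50]), small_model.vocabulary)
        for outcome in ("hospitalization", "mortality"):
            members = getattr(small_model, outcome)
            stacked = np.stack([m.predict_proba(X)[:, 1] for m in members])
            ensemble = small_model.predict_proba_matrix(X, outcome)
            assert (ensemble >= stacked.min(axis=0) - 1e-12).all()
            assert (ensemble <= stacked.max(axis=0) + 1e-12).all()
            assert ((ensemble >= 0) & (ensemble <= 1)).all()


def test_model_save_load_round_trips_predictions(small_model, small_corpus, tmp_path):
    X, _, _ = build_training_matrices(list(small_corpus[:20]), small_model.vocabulary)
    path = tmp_path / "model.joblib"
    small_model.save(path)
    reloaded = SeverityModel.load(path)
    for outcome in ("hospitalization", "mortality"):
        assert np.array_equal(
            small_model.predict_proba_matrix(X, outcome),
            reloaded.predict_proba_matrix(X, outcome),
        )
    assert reloaded.vocabulary == small_model.vocabulary
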