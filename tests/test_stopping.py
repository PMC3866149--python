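"""Feature extraction, score regression and confidence tables."""

import numpy as np
import pytest

import phenolearn as pl
from phenolearn.stopping import (
    N_BASE_FEATURES,
    build_design,
    expand_row,
    score_bin,
)

from conftest import matrix


class TestExtractFeatures:
    def test_self_comparison_of_identical_models(self):
        truth = matrix([[1, 1, 2], [2, 2, 1], [1, 1, 2]], m=2)
        model = pl.greedy_merge(truth, variant="full")
        f = pl.extract_features(
            model, model, prev_batch=[], sigma=truth, batch_index=2
        )
        assert f[0] == 2
        assert f[1] == model.n_distributions
        assert f[2] == 2  # two phenotype codes observed
        assert f[3] == 9  # all 9 predictions agree with themselves
        assert f[9] == model.n_distributions  # perfect matching
        assert f[5] == f[6] == 0.0  # empty previous batch covers nothing

    def test_batch_index_below_two_rejected(self):
        truth = matrix([[1]], m=1)
        model = pl.greedy_merge(truth, variant="full")
        with pytest.raises(ValueError):
            pl.extract_features(model, model, [], truth, batch_index=1)

    def test_matching_oracle_on_two_by_two_compatibility(self):
        space = pl.ExperimentSpace.default(3, 2, 5)
        prev = pl.Model(
            space,
            {0: {0: 1, 1: 2}, 1: {2: 4}},
            {(0, 0): frozenset([0]), (1, 0): frozenset([0]), (2, 1): frozenset([1])},
        )
        curr = pl.Model(
            space,
            {0: {0: 1, 1: 3}, 1: {2: 4, 0: 1}},
            {(0, 0): frozenset([1]), (1, 0): frozenset([0]), (2, 1): frozenset([1])},
        )
        # enumerate compatibilities by hand: prev0-curr0 conflict on t2 (2 vs
        # 3); prev0-curr1 agree on t1; prev1-curr1 agree on t3; prev1-curr0
        # share nothing -> maximum matching has size 1
        assert pl.distribution_matching(prev, curr) == 1

    def test_batch_coverage_fractions(self):
        truth = matrix([[1, 1], [1, 1]], m=2)
        model = pl.greedy_merge(truth, variant="full")  # one distribution
        f = pl.extract_features(
            model, model, prev_batch=[(0, 0), (1, 1)], sigma=truth, batch_index=3
        )
        # best single condition covers 1 of 2 supported targets
        assert f[5] == f[6] == pytest.approx(0.5)
        # 2 of 4 valued cells arrived in the previous batch
        assert f[7] == pytest.approx(0.5)


class TestBuildDesign:
    def test_ten_features_expand_to_fifty_five_columns(self, rng):
        F = rng.normal(size=(30, N_BASE_FEATURES))
        X, kept, means, sds = build_design(F)
        assert len(kept) == 55
        assert X.shape == (30, 55)
        assert np.allclose(X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(X.std(axis=0), 1, atol=1e-9)

    def test_constant_column_is_dropped_and_recorded(self, rng):
        F = rng.normal(size=(20, N_BASE_FEATURES))
        F[:, 3] = 7.0
        X, kept, *_ = build_design(F)
        assert 3 not in kept
        assert X.shape[1] < 55

    def test_expand_row_matches_design_expansion(self, rng):
        F = rng.normal(size=(5, N_BASE_FEATURES))
        _, kept, means, sds = build_design(F)
        row = expand_row(F[2])
        assert row.size == 55

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            build_design(np.ones((1, 10)))


class TestFitScoreModel:
    def _synthetic(self, rng, n=500, slope=1.2):
        F = rng.normal(size=(n, N_BASE_FEATURES))
        z0 = (F[:, 0] - F[:, 0].mean()) / F[:, 0].std()
        lp = slope * z0 + 0.3
        lp = lp + rng.normal(scale=0.05 * lp.std(), size=n)
        adjusted = 2 / (1 + np.exp(-lp)) - 1
        frac = rng.uniform(0.2, 0.8, size=n)
        return F, adjusted + frac, frac

    def test_recovers_a_planted_linear_response(self, rng):
        F, acc, frac = self._synthetic(rng)
        model = pl.fit_score_model(F, acc, frac)
        assert 0 in [model.kept[j] for j in model.selected]  # feature 1 found
        pos = [model.kept[j] for j in model.selected].index(0)
        assert model.coef[pos] == pytest.approx(1.2, rel=0.05)

    def test_pure_noise_gives_near_empty_selection(self, rng):
        F = rng.normal(size=(200, N_BASE_FEATURES))
        frac = rng.uniform(0.2, 0.8, size=200)
        acc = frac + rng.normal(scale=0.01, size=200)
        model = pl.fit_score_model(F, acc, frac)
        # any surviving features carry negligible weight ...
        assert np.abs(model.coef).sum() < 0.05
        # ... so scores reduce to the observed fraction up to normalization
        scores = model.training_scores
        assert np.corrcoef(scores, frac)[0, 1] > 0.95

    def test_row_permutation_keeps_selection_for_fixed_cv_seed(self, rng):
        F, acc, frac = self._synthetic(rng, n=120)
        m1 = pl.fit_score_model(F, acc, frac, cv_seed=7)
        perm = rng.permutation(120)
        m2 = pl.fit_score_model(F[perm], acc[perm], frac[perm], cv_seed=7)
        assert [m1.kept[j] for j in m1.selected] == [m2.kept[j] for j in m2.selected]

    def test_degenerate_response_rejected(self, rng):
        F = rng.normal(size=(30, N_BASE_FEATURES))
        frac = np.full(30, 0.5)
        with pytest.raises(ValueError):
            pl.fit_score_model(F, frac + 0.1, frac)
        with pytest.raises(ValueError):
            pl.fit_score_model(F[:5], frac[:5] + 0.1, frac[:5])


class TestPredictedScore:
    def test_training_maximum_row_scores_exactly_one(self, rng):
        F = rng.normal(size=(100, N_BASE_FEATURES))
        frac = rng.uniform(0.1, 0.9, size=100)
        acc = np.clip(frac + rng.uniform(0, 0.2, size=100), 0, 1)
        model = pl.fit_score_model(F, acc, frac)
        assert model.training_scores.max() == pytest.approx(1.0)
        assert (model.training_scores <= 1.0 + 1e-12).all()

    def test_zero_linear_predictor_reduces_to_observed_fraction(self):
        model = pl.ScoreModel(
            kept=list(range(55)),
            means=np.zeros(55),
            sds=np.ones(55),
            selected=[],
            coef=np.zeros(0),
            intercept=0.0,
            normalizer=1.25,
        )
        f = np.zeros(N_BASE_FEATURES)
        assert pl.predicted_score(model, f, 0.5) == pytest.approx(0.5 / 1.25)

    def test_score_is_monotone_in_the_linear_predictor(self):
        model = pl.ScoreModel(
            kept=list(range(55)),
            means=np.zeros(55),
            sds=np.ones(55),
            selected=[0],
            coef=np.array([1.0]),
            intercept=0.0,
            normalizer=1.1,
        )
        feats = [np.r_[x, np.zeros(N_BASE_FEATURES - 1)] for x in (-2, -1, 0, 1, 2)]
        scores = [pl.predicted_score(model, f, 0.4) for f in feats]
        assert scores == sorted(scores)

    def test_json_round_trip(self, tmp_path, rng):
        F = rng.normal(size=(60, N_BASE_FEATURES))
        frac = rng.uniform(0.2, 0.8, size=60)
        acc = np.clip(frac + 0.1 + rng.normal(scale=0.02, size=60), 0, 1)
        model = pl.fit_score_model(F, acc, frac)
        path = tmp_path / "score.json"
        model.to_json(path)
        back = pl.ScoreModel.from_json(path)
        f = F[7]
        assert pl.predicted_score(back, f, 0.5) == pytest.approx(
            pl.predicted_score(model, f, 0.5)
        )


class TestConfidenceTables:
    def test_perfect_accuracy_gives_full_confidence(self):
        scores = np.array([0.5, 0.7, 0.9])
        tables = pl.confidence_tables(scores, np.ones(3), np.array([2, 3, 4]))
        assert all(v == 1.0 for v in tables.by_score.values())

    def test_always_overconfident_scores_give_zero(self):
        accs = np.array([0.5, 0.6])
        scores = accs + 0.05
        tables = pl.confidence_tables(scores, accs, np.array([2, 2]))
        assert all(v == 0.0 for v in tables.by_score.values())

    def test_empty_bins_are_absent_not_zero(self):
        tables = pl.confidence_tables(
            np.array([0.505, 0.905]), np.array([0.6, 0.95]), np.array([2, 3])
        )
        assert set(tables.by_score) == {50, 90}
        assert (2, 50) in tables.by_batch_score
        assert (3, 90) in tables.by_batch_score

    def test_json_round_trip(self, tmp_path):
        tables = pl.confidence_tables(
            np.array([0.5, 0.8]), np.array([0.9, 0.7]), np.array([2, 5])
        )
        path = tmp_path / "tables.json"
        tables.to_json(path)
        back = pl.ConfidenceTables.from_json(path)
        assert back.by_score == tables.by_score
        assert back.by_batch_score == tables.by_batch_score

    def test_score_binning_is_one_percent(self):
        assert score_bin(0.701) == 70
        assert score_bin(0.7) == 70
        assert score_bin(1.0) == 100
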