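"""Initial design, ranking, batch selection and the learning loop."""

import numpy as np
import pytest
from scipy import stats

import phenolearn as pl
from phenolearn.core import ImputationRelation

from conftest import matrix


class TestInitialDesign:
    def test_square_space_two_batches_first_is_unperturbed_column(self):
        space = pl.ExperimentSpace.default(100, 100, 4)
        batches = pl.initial_design(space, 100, seed=1)
        assert len(batches) == 2
        assert batches[0] == [(t, 0) for t in range(100)]

    def test_rectangular_space_covers_all_targets_and_conditions(self):
        space = pl.ExperimentSpace.default(10, 5, 3)
        batches = pl.initial_design(space, 10, seed=2)
        assert len(batches) == 2  # ceil((10 + 10) / 10)
        cells = [e for b in batches for e in b]
        assert len(cells) == len(set(cells)) == 20
        assert {c for _, c in cells} == set(range(5))
        assert {t for t, _ in cells} == set(range(10))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_every_target_observed_at_least_twice(self, seed):
        space = pl.ExperimentSpace.default(12, 9, 3)
        cells = [e for b in pl.initial_design(space, 7, seed=seed) for e in b]
        counts = np.bincount([t for t, _ in cells], minlength=12)
        assert (counts >= 2).all()
        assert len(cells) == len(set(cells))

    def test_space_too_small_for_design_is_an_error(self):
        space = pl.ExperimentSpace.default(2, 2, 2)
        with pytest.raises(ValueError):
            pl.initial_design(space, 3, seed=0)


class TestRanking:
    def _setup(self, with_imputation):
        sigma = matrix([[1, 1, 0], [2, 2, 0]], m=3)
        model = pl.greedy_merge(sigma, variant="full")
        rel, part = pl.build_imputations(
            model, sigma, "both" if with_imputation else "none"
        )
        return sigma, model, rel, part

    def test_rank_formula_invariant_holds_for_all_entries(self):
        sigma, model, rel, part = self._setup(True)
        table = pl.rank_experiments(model, sigma, rel, part)
        for (zp, w, z) in table.entries.values():
            assert w in (0, 1)
            assert z == (w + 1 if zp == 1 else w + zp + 3)

    def test_no_imputation_cells_rank_above_single_imputation(self):
        # z' = 0 -> z = W + 3 in {3, 4}; z' = 1 -> z = W + 1 in {1, 2}:
        # unexplored cells always outrank singly-imputed ones
        sigma, model, rel, part = self._setup(True)
        table = pl.rank_experiments(model, sigma, rel, part)
        zs_single = [z for zp, _, z in table.entries.values() if zp == 1]
        zs_none = [z for zp, _, z in table.entries.values() if zp == 0]
        if zs_single and zs_none:
            assert min(zs_none) > max(zs_single)
        for zp, _, z in table.entries.values():
            if zp >= 2:  # multi-imputation cells outrank everything else
                assert z >= 5

    def test_all_unobserved_cells_are_ranked(self):
        sigma, model, rel, part = self._setup(False)
        table = pl.rank_experiments(model, sigma, rel, part)
        unobserved = {(t, c) for t in range(2) for c in range(3)
                      if sigma.values[t, c] == 0}
        assert set(table.entries) == unobserved


class TestSelectBatch:
    def test_batch_is_disjoint_from_observations_and_right_sized(self):
        truth, _ = pl.generate(
            pl.GenerationParams(m=4, lambda_r=0.8, lambda_u=0.4, N=12, seed=0)
        )
        sigma = pl.PhenotypeMatrix(truth.space)
        for batch in pl.initial_design(truth.space, 12, seed=0):
            for t, c in batch:
                sigma.values[t, c] = truth.values[t, c]
        model = pl.greedy_merge(sigma, variant="full")
        rel, part = pl.build_imputations(model, sigma, "both")
        table = pl.rank_experiments(model, sigma, rel, part)
        batch = pl.select_batch(table, part, model, 12, seed=5)
        assert len(batch) == len(set(batch)) == 12
        for t, c in batch:
            assert sigma.values[t, c] == 0

    def test_equivalent_target_suppressed_within_pass(self):
        # two equivalent targets, one condition unobserved for both; a batch
        # of one must not be blocked, and a batch of two must lift the
        # suppression to fill up
        sigma = matrix([[1, 2, 0], [1, 2, 0]], m=2)
        model = pl.greedy_merge(sigma, variant="full")
        rel, part = pl.build_imputations(model, sigma, "equiv")
        table = pl.rank_experiments(model, sigma, rel, part)
        assert set(table.entries) == {(0, 2), (1, 2)}
        picks = pl.select_batch(table, part, model, 2, seed=0)
        assert set(picks) == {(0, 2), (1, 2)}

    def test_final_short_batch_returns_remainder(self):
        sigma = matrix([[1, 0], [1, 1]], m=2)
        model = pl.greedy_merge(sigma, variant="full")
        rel, part = pl.build_imputations(model, sigma, "none")
        table = pl.rank_experiments(model, sigma, rel, part)
        batch = pl.select_batch(table, part, model, 5, seed=0)
        assert batch == [(0, 1)]


class TestRandomBatch:
    def test_remainder_returned_when_short(self):
        sigma = matrix([[1, 0], [1, 1]], m=2)
        assert pl.random_batch(sigma, 5, seed=0) == [(0, 1)]

    def test_reproducible_given_seed(self):
        sigma = matrix([[0, 0, 0], [0, 1, 0]], m=2)
        assert pl.random_batch(sigma, 3, seed=9) == pl.random_batch(sigma, 3, seed=9)

    def test_marginal_inclusion_is_uniform(self):
        sigma = matrix([[0] * 5] * 4, m=2)
        sigma.values[0, 0] = 1
        counts = np.zeros((4, 5))
        rng = np.random.default_rng(0)
        n_draws = 10_000
        for _ in range(n_draws):
            for t, c in pl.random_batch(sigma, 3, rng):
                counts[t, c] += 1
        observed = counts[sigma.values == 0]
        assert stats.chisquare(observed).pvalue > 1e-3


class TestRunLearning:
    def test_single_full_batch_reaches_perfect_accuracy(self):
        truth, _ = pl.generate(
            pl.GenerationParams(m=3, lambda_r=0.7, lambda_u=0.5, N=6, seed=1)
        )
        cfg = pl.LearnerConfig(batch_size=36, seed=0)
        trace = pl.run_learning(truth, cfg)
        assert len(trace.rows) == 1
        assert trace.rows[0]["accuracy"] == 1.0

    @pytest.mark.parametrize("learner", ["active", "random"])
    def test_observation_counts_grow_by_batch_size(self, learner):
        truth, _ = pl.generate(
            pl.GenerationParams(m=4, lambda_r=0.8, lambda_u=0.4, N=10, seed=2)
        )
        cfg = pl.LearnerConfig(learner=learner, batch_size=10, seed=3)
        trace = pl.run_learning(truth, cfg)
        ns = [r["n_observed"] for r in trace.rows]
        diffs = np.diff(ns)
        assert all(d == 10 for d in diffs[:-1])  # exactly S until the end
        if len(diffs):
            assert 0 < diffs[-1] <= 10

    def test_exhaustive_fallback_reaches_one(self):
        truth, _ = pl.generate(
            pl.GenerationParams(m=6, lambda_r=0.9, lambda_u=0.9, N=6, seed=5)
        )
        for learner in ("active", "random"):
            cfg = pl.LearnerConfig(
                learner=learner, imputation="none", batch_size=6, seed=1
            )
            trace = pl.run_learning(truth, cfg)
            assert trace.final_accuracy == 1.0

    def test_random_accuracy_at_least_observed_fraction(self):
        # observed cells are always predicted correctly, so accuracy grows at
        # least linearly in the observed fraction
        truth, _ = pl.generate(
            pl.GenerationParams(m=4, lambda_r=0.6, lambda_u=0.6, N=8, seed=7)
        )
        cfg = pl.LearnerConfig(learner="random", batch_size=8, seed=2)
        trace = pl.run_learning(truth, cfg)
        for row in trace.rows:
            assert row["accuracy"] >= row["fraction_observed"] - 1e-12

    def test_trace_round_trips_through_csv(self, tmp_path):
        truth, _ = pl.generate(
            pl.GenerationParams(m=3, lambda_r=0.7, lambda_u=0.4, N=6, seed=3)
        )
        trace = pl.run_learning(truth, pl.LearnerConfig(batch_size=9, seed=0))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back["batch"]) == [r["batch"] for r in trace.rows]
        assert np.allclose(back["accuracy"], [r["accuracy"] for r in trace.rows])

    def test_bcluster_structure_also_learns(self):
        truth, _ = pl.generate(
            pl.GenerationParams(m=3, lambda_r=0.8, lambda_u=0.6, N=5, seed=6)
        )
        cfg = pl.LearnerConfig(
            structure="bcluster", imputation="threepoint", batch_size=5, seed=1
        )
        trace = pl.run_learning(truth, cfg)
        assert trace.final_accuracy == 1.0
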