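import numpy as np
import pandas as pd
import pytest

import leukopred as lp
from conftest import prepare
from leukopred.classify import ElasticNetGrid, RandomForestGrid
from leukopred.selection import _selection_glm_grid, _selection_rf_grid


def make_xy(n=28, n_noise=40, separating=True, seed=0, duplicate=False):
    """Small standardized design with one (optionally duplicated) separating gene."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    cols = {}
    if separating:
        signal = np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.05, n)
        cols["SIG1"] = signal
        if duplicate:
            cols["SIG2"] = signal.copy()
    for i in range(n_noise):
        cols[f"N{i:03d}"] = rng.normal(0, 1.0, n)
    X = pd.DataFrame(cols)
    X = (X - X.mean()) / X.std(ddof=1)
    return X, y


class TestGlmRank:
    def test_separating_gene_ranks_first(self):
        top1 = 0
        for seed in range(10):
            X, y = make_xy(seed=seed)
            order = lp.glm_rank(X, y, _selection_glm_grid(), folds=7, seed=seed)
            top1 += order[0] == "SIG1"
        assert top1 >= 9

    def test_duplicated_informative_genes_adjacent_in_id_order(self):
        X, y = make_xy(seed=1, duplicate=True)
        order = lp.glm_rank(X, y, _selection_glm_grid(), folds=7, seed=1)
        assert set(order[:2]) == {"SIG1", "SIG2"}
        # identical columns tie on |coef| and |corr|; gene id breaks the tie
        assert order.index("SIG1") < order.index("SIG2")

    def test_all_constant_matrix_rejected(self):
        X = pd.DataFrame(np.zeros((20, 5)), columns=list("abcde"))
        y = np.array([1] * 10 + [0] * 10)
        with pytest.raises(ValueError, match="constant"):
            lp.glm_rank(X, y, _selection_glm_grid(), folds=5, seed=0)

    def test_fold_infeasible_class_sizes_rejected(self):
        X, y = make_xy(n=10, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            lp.glm_rank(X, y, _selection_glm_grid(), folds=7, seed=0)

    def test_deterministic_given_seed(self):
        X, y = make_xy(seed=2)
        a = lp.glm_rank(X, y, _selection_glm_grid(), folds=7, seed=5)
        b = lp.glm_rank(X, y, _selection_glm_grid(), folds=7, seed=5)
        assert a == b


class TestRfRank:
    def test_interacting_pair_enriched_above_noise(self):
        # XOR-style pair carries only interaction signal; across seeds its
        # mean importance rank should beat the pure-noise genes' mean rank
        grid = RandomForestGrid(n_estimators=300, cv_n_estimators=25)
        pair_ranks, noise_ranks = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 28
            a = rng.choice([-1.0, 1.0], n)
            b = rng.choice([-1.0, 1.0], n)
            y = ((a * b) > 0).astype(int)
            if min(y.sum(), n - y.sum()) < 7:
                continue
            cols = {"XA": a + rng.normal(0, 0.1, n), "XB": b + rng.normal(0, 0.1, n)}
            for i in range(18):
                cols[f"N{i:02d}"] = rng.normal(0, 1, n)
            X = pd.DataFrame(cols)
            order = lp.rf_rank(X, y, grid=grid, folds=7, seed=seed)
            pair_ranks += [order.index("XA"), order.index("XB")]
            noise_ranks += [order.index(c) for c in X.columns if c.startswith("N")]
        assert len(pair_ranks) >= 10
        assert np.mean(pair_ranks) < np.mean(noise_ranks)

    def test_single_candidate_returned(self):
        X, y = make_xy(seed=3)
        assert lp.rf_rank(X, y, ["N000"], folds=7, seed=0) == ["N000"]

    def test_deterministic_given_seed(self):
        X, y = make_xy(seed=4)
        a = lp.rf_rank(X, y, grid=_selection_rf_grid(), folds=7, seed=9)
        b = lp.rf_rank(X, y, grid=_selection_rf_grid(), folds=7, seed=9)
        assert a == b

    def test_unknown_candidate_rejected(self):
        X, y = make_xy(seed=5)
        with pytest.raises(KeyError, match="NOPE"):
            lp.rf_rank(X, y, ["NOPE"], folds=7, seed=0)


class TestRunSelection:
    def small_config(self, **kwargs):
        defaults = dict(n_iterations=4, top_glm=30, top_rf_first=15, top_rf_final=3,
                        vote_threshold=2, cv_folds=5, base_seed=0)
        defaults.update(kwargs)
        return lp.SelectionConfig(**defaults)

    def test_degenerate_single_iteration_returns_top_list(self):
        X, y = make_xy(seed=6)
        cfg = self.small_config(n_iterations=1, vote_threshold=0,
                                subsample_fraction=1.0)
        res = lp.run_selection(X, y, cfg)
        assert sorted(res.final_features) == sorted(res.iteration_lists[0])

    def test_votes_conserve_audit_trail(self):
        X, y = make_xy(seed=7)
        res = lp.run_selection(X, y, self.small_config())
        for gene, v in res.votes.items():
            assert v == sum(gene in lst for lst in res.iteration_lists)
        assert sum(res.votes) == sum(len(lst) for lst in res.iteration_lists)
        assert all(len(lst) <= 3 for lst in res.iteration_lists)
        assert set(res.final_features) <= set().union(*map(set, res.iteration_lists))

    def test_raising_vote_threshold_shrinks_final_set(self):
        X, y = make_xy(seed=8)
        res = lp.run_selection(X, y, self.small_config(vote_threshold=0))
        previous = set(res.final_features)
        for thr in (1, 2, 3):
            cur = set(
                lp.run_selection(X, y, self.small_config(vote_threshold=thr)).final_features
            )
            assert cur <= previous
            previous = cur

    def test_bit_reproducible(self):
        X, y = make_xy(seed=9)
        cfg = self.small_config()
        a, b = lp.run_selection(X, y, cfg), lp.run_selection(X, y, cfg)
        pd.testing.assert_series_equal(a.votes, b.votes)
        assert a.iteration_lists == b.iteration_lists
        assert a.final_features == b.final_features

    def test_planted_markers_recovered_in_study_shaped_cohort(self, planted_cohort):
        parts = prepare(planted_cohort)
        cfg = lp.SelectionConfig(n_iterations=6, vote_threshold=3, base_seed=0)
        res = lp.run_selection(parts["z_train"], parts["y_train"], cfg)
        recovery = lp.truth_recovery_report(res.final_features, planted_cohort.truth)
        assert recovery["recall"] == 1.0

    def test_invalid_config_rejected(self):
        X, y = make_xy(seed=0)
        with pytest.raises(ValueError, match="vote_threshold"):
            lp.run_selection(X, y, self.small_config(vote_threshold=10, n_iterations=4))
        with pytest.raises(ValueError, match="top_rf_final"):
            lp.run_selection(X, y, self.small_config(top_rf_final=40, top_rf_first=15))

    def test_ladder_truncates_when_top_glm_exceeds_genes(self):
        X, y = make_xy(n_noise=10, seed=1)  # 11 genes < top_glm
        res = lp.run_selection(X, y, self.small_config())
        assert all(len(lst) == 3 for lst in res.iteration_lists)
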