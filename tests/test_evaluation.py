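"""Ranking metrics, fold plans, grid search, nested CV, paired t-tests."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from adrpred.evaluation import (
    EvalReport,
    HyperGrid,
    SingleClassError,
    aupr,
    auroc,
    compare_reports,
    cross_validate,
    grid_search_cv,
    make_folds,
    nested_cv,
    paired_t_test,
    pool_and_score,
)
from adrpred.matrixdata import InteractionMatrix
from adrpred.models import NaiveSpec, PredictionMatrix, Predictor, naive_fit_predict

from conftest import random_interaction


# --- independent metric oracles -------------------------------------------


def auroc_pairwise(y, s):
    """Exhaustive positive-negative pair counting with half-credit ties."""
    pos, neg = s[y == 1], s[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def aupr_blocks(y, s):
    """Step-wise average precision with tied scores handled as one block."""
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    ap, tp, i = 0.0, 0, 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        block_tp = y[i:j].sum()
        tp += block_tp
        ap += (tp / j) * block_tp
        i = j
    return ap / y.sum()


class RecordingNaive(Predictor):
    """Naive predictor that logs every (train, validation) drug split."""

    name = "naive"

    def __init__(self):
        super().__init__()
        self.calls: list[tuple[tuple, tuple]] = []

    def iter_grid(self, grid):
        return [{}]

    def fit_predict(self, Y_known, new_drug_ids, params, seed=0):
        self.calls.append((tuple(Y_known.drug_ids), tuple(new_drug_ids)))
        return naive_fit_predict(Y_known, new_drug_ids)


class TestMetrics:
    def test_perfect_ranking_gives_unit_scores(self):
        y, s = np.array([1, 0]), np.array([0.9, 0.1])
        assert aupr(y, s) == 1.0
        assert auroc(y, s) == 1.0

    def test_reversed_ranking_single_positive(self):
        y, s = np.array([1, 0]), np.array([0.1, 0.9])
        assert aupr(y, s) == pytest.approx(0.5)
        assert auroc(y, s) == 0.0

    def test_constant_scores_give_prevalence_and_half(self):
        y = np.array([1, 0, 0, 0, 1])
        s = np.full(5, 0.7)
        assert aupr(y, s) == pytest.approx(2 / 5)
        assert auroc(y, s) == pytest.approx(0.5)

    def test_matches_pairwise_and_block_oracles(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert abs(auroc(y, s) - auroc_pairwise(y, s)) < 1e-12
            assert abs(aupr(y, s) - aupr_blocks(y, s)) < 1e-12

    def test_monotone_transform_leaves_metrics_unchanged(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        t = np.exp(2.0 * s) + 5.0  # strictly increasing
        assert abs(aupr(y, s) - aupr(y, t)) < 1e-12
        assert abs(auroc(y, s) - auroc(y, t)) < 1e-12

    def test_single_class_labels_rejected(self):
        with pytest.raises(SingleClassError):
            auroc(np.ones(4), np.arange(4.0))
        with pytest.raises(SingleClassError):
            aupr(np.zeros(4), np.arange(4.0))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        # scores on a 0.01 grid so the affine transform below cannot merge
        # distinct scores through float absorption
        st.tuples(st.integers(0, 1), st.integers(-500, 500)),
        min_size=4,
        max_size=40,
    ),
    st.floats(0.1, 3.0),
)
def test_metrics_bounded_and_transform_invariant(pairs, scale):
    """AUPR/AUROC live in [0,1] and ignore strictly increasing rescaling."""
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs]) / 100.0
    assume(0 < y.sum() < y.size)
    a, r = aupr(y, s), auroc(y, s)
    assert 0.0 <= a <= 1.0 and 0.0 <= r <= 1.0
    t = scale * s + 2.0
    assert abs(aupr(y, t) - a) < 1e-12
    assert abs(auroc(y, t) - r) < 1e-12


class TestPoolAndScore:
    def test_perfect_two_by_two(self):
        truth = InteractionMatrix([[1, 0], [0, 1]], ["a1", "a2"], ["n1", "n2"])
        scores = PredictionMatrix(
            np.array([[0.9, 0.1], [0.2, 0.8]]), ["a1", "a2"], ["n1", "n2"]
        )
        assert pool_and_score(truth, scores) == (1.0, 1.0)

    def test_constant_scores_pool_to_half_auroc(self):
        truth = InteractionMatrix([[1, 0], [0, 1]], ["a1", "a2"], ["n1", "n2"])
        scores = PredictionMatrix(np.full((2, 2), 0.3), ["a1", "a2"], ["n1", "n2"])
        assert pool_and_score(truth, scores)[1] == pytest.approx(0.5)

    def test_equals_manual_flattening(self, rng):
        truth = random_interaction(rng, m=10, n=6, prefix="t")
        if truth.values.sum() in (0, truth.values.size):
            pytest.skip("degenerate draw")
        pred = PredictionMatrix(
            rng.normal(size=(10, 6)), truth.adr_ids, truth.drug_ids
        )
        a, r = pool_and_score(truth, pred)
        assert a == pytest.approx(aupr(truth.values.ravel(), pred.scores.ravel()))
        assert r == pytest.approx(auroc(truth.values.ravel(), pred.scores.ravel()))

    def test_index_mismatch_rejected(self, rng):
        truth = random_interaction(rng, m=4, n=3)
        pred = PredictionMatrix(np.zeros((4, 3)), truth.adr_ids, ["x", "y", "z"])
        with pytest.raises(ValueError, match="indexed differently"):
            pool_and_score(truth, pred)


class TestMakeFolds:
    def test_twenty_drugs_five_equal_folds(self):
        plan = make_folds([f"d{i}" for i in range(20)], 5, seed=0)
        sizes = sorted(len(plan.fold_drugs(f)) for f in range(5))
        assert sizes == [4, 4, 4, 4, 4]

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = make_folds([f"d{i}" for i in range(22)], 5, seed=0)
        sizes = sorted(len(plan.fold_drugs(f)) for f in range(5))
        assert sizes == [4, 4, 4, 5, 5]

    def test_same_seed_identical_assignment(self):
        ids = [f"d{i}" for i in range(17)]
        assert make_folds(ids, 4, 3).assignments == make_folds(ids, 4, 3).assignments

    def test_every_drug_assigned_exactly_once(self):
        ids = [f"d{i}" for i in range(13)]
        plan = make_folds(ids, 4, 1)
        assert sorted(plan.assignments) == sorted(ids)
        covered = [d for f in range(4) for d in plan.fold_drugs(f)]
        assert sorted(covered) == sorted(ids)

    def test_too_few_folds_or_drugs_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["d1", "d2"], 1, 0)
        with pytest.raises(ValueError):
            make_folds(["d1", "d2"], 3, 0)


class TestPairedTTest:
    def test_identical_vectors_give_p_one(self):
        assert paired_t_test([0.4, 0.5, 0.6], [0.4, 0.5, 0.6]) == 1.0

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.uniform(size=6), rng.uniform(size=6)
        assert paired_t_test(a, b) == pytest.approx(paired_t_test(b, a))

    def test_constant_nonzero_shift_gives_p_zero(self):
        a = np.array([0.40, 0.42, 0.41, 0.43, 0.39])
        assert paired_t_test(a, a + 0.02) == 0.0

    def test_matches_textbook_formula(self):
        import scipy.stats

        a = np.array([0.40, 0.42, 0.41, 0.43, 0.39])
        b = np.array([0.43, 0.41, 0.44, 0.47, 0.40])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * scipy.stats.t.sf(abs(t), df=len(d) - 1)
        assert paired_t_test(a, b) == pytest.approx(p, rel=1e-12)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([0.4], [0.5])


class TestGridSearch:
    def test_single_combination_grid_returns_it(self, small_bench):
        from adrpred.models import KRSpec

        spec = KRSpec([small_bench.X_all])
        grid = HyperGrid(lambda_values=(1.0,), sigma_values=(5.0,))
        best, table = grid_search_cv(spec, small_bench.Y_known, grid, 3, seed=0)
        assert best == {"lam": 1.0, "sigma": 5.0}
        assert len(table) == 1

    def test_duplicated_combinations_deduplicated(self, small_bench):
        from adrpred.models import KRSpec

        class DupKR(KRSpec):
            def iter_grid(self, grid):
                combos = super().iter_grid(grid)
                return combos + combos

        grid = HyperGrid(lambda_values=(0.1, 1.0), sigma_values=(5.0,))
        a, t1 = grid_search_cv(
            KRSpec([small_bench.X_all]), small_bench.Y_known, grid, 3, seed=0
        )
        b, t2 = grid_search_cv(
            DupKR([small_bench.X_all]), small_bench.Y_known, grid, 3, seed=0
        )
        assert a == b and len(t1) == len(t2)

    def test_argmax_matches_external_loop_oracle(self, small_bench):
        from adrpred.evaluation import _derive_seed, _tie_break_key
        from adrpred.models import KRSpec

        spec = KRSpec([small_bench.X_all])
        grid = HyperGrid(lambda_values=(0.1, 10.0), sigma_values=(3.0, 10.0))
        Y = small_bench.Y_known
        best, _ = grid_search_cv(spec, Y, grid, 3, seed=4)

        # independent loop: recompute every combination outside the harness
        plan = make_folds(Y.drug_ids, 3, seed=4)
        from adrpred.matrixdata import mask_new_drugs

        scores = {}
        for lam in (0.1, 10.0):
            for sig in (3.0, 10.0):
                vals = []
                for f in range(3):
                    val_ids = plan.fold_drugs(f)
                    Yk, Yt = mask_new_drugs(Y, val_ids)
                    pred = spec.fit_predict(
                        Yk, val_ids, {"lam": lam, "sigma": sig},
                        seed=_derive_seed(4, f),
                    )
                    vals.append(pool_and_score(Yt, pred)[0])
                scores[(lam, sig)] = np.mean(vals)
        oracle_best = max(
            scores,
            key=lambda k: (scores[k],) + _tie_break_key({"lam": k[0], "sigma": k[1]}),
        )
        assert (best["lam"], best["sigma"]) == oracle_best

    def test_tie_break_prefers_larger_lambda(self, small_bench):
        class ConstantScoreKR(NaiveSpec):
            name = "const"

            def iter_grid(self, grid):
                return [{"lam": lam, "sigma": 1.0} for lam in grid.lambda_values]

        grid = HyperGrid(lambda_values=(0.1, 1.0, 10.0), sigma_values=(1.0,))
        best, _ = grid_search_cv(
            ConstantScoreKR(), small_bench.Y_known, grid, 3, seed=0
        )
        assert best["lam"] == 10.0


class TestNestedCV:
    def test_outer_folds_partition_drugs(self, small_bench):
        Y = small_bench.Y_known
        plan = make_folds(Y.drug_ids, 5, seed=2)
        covered = sorted(d for f in range(5) for d in plan.fold_drugs(f))
        assert covered == sorted(Y.drug_ids)

    def test_no_validation_drug_enters_training(self, small_bench):
        Y = small_bench.Y_known
        rec = RecordingNaive()
        nested_cv(rec, Y, HyperGrid(), outer=4, inner=3, seed=2)
        plan = make_folds(Y.drug_ids, 4, seed=2)
        outer_vals = [set(plan.fold_drugs(f)) for f in range(4)]
        for train_ids, val_ids in rec.calls:
            assert not set(train_ids) & set(val_ids)
            matching = [v for v in outer_vals if set(val_ids) == v]
            if not matching:  # inner call: must stay inside one outer-training set
                inside = [
                    v for v in outer_vals
                    if not (set(train_ids) | set(val_ids)) & v
                ]
                assert inside, "inner split leaks an outer validation drug"

    def test_inner_folds_partition_outer_training_set(self, small_bench):
        from adrpred.evaluation import _derive_seed

        Y = small_bench.Y_known
        outer_plan = make_folds(Y.drug_ids, 5, seed=9)
        for f in range(5):
            train = outer_plan.train_drugs(f)
            inner_plan = make_folds(train, 4, _derive_seed(9, f))
            covered = sorted(d for g in range(4) for d in inner_plan.fold_drugs(g))
            assert covered == sorted(train)

    def test_naive_nested_equals_plain_cv(self, small_bench):
        Y = small_bench.Y_known
        nested = nested_cv(NaiveSpec(), Y, HyperGrid(), outer=5, inner=3, seed=6)
        plain = cross_validate(NaiveSpec(), Y, {}, n_folds=5, seed=6)
        np.testing.assert_allclose(nested.auprs, plain.auprs)
        np.testing.assert_allclose(nested.aurocs, plain.aurocs)

    def test_identical_seed_gives_identical_folds_across_methods(self, small_bench):
        Y = small_bench.Y_known
        rec1, rec2 = RecordingNaive(), RecordingNaive()
        rec2.name = "other"
        nested_cv(rec1, Y, HyperGrid(), outer=4, inner=3, seed=11)
        nested_cv(rec2, Y, HyperGrid(), outer=4, inner=3, seed=11)
        assert rec1.calls == rec2.calls

    def test_report_means_are_fold_averages(self, small_bench):
        rep = nested_cv(NaiveSpec(), small_bench.Y_known, HyperGrid(),
                        outer=4, inner=3, seed=0)
        assert rep.mean_aupr == pytest.approx(np.mean(rep.auprs), abs=1e-12)
        assert rep.mean_auroc == pytest.approx(np.mean(rep.aurocs), abs=1e-12)
        assert np.all((rep.auprs >= 0) & (rep.auprs <= 1))
        assert np.all((rep.aurocs >= 0) & (rep.aurocs <= 1))


class TestCompareReports:
    def _report(self, method, seed, shift=0.0):
        per_fold = [
            {"fold": f, "aupr": 0.3 + 0.01 * f + shift,
             "auroc": 0.8 + 0.005 * f + shift, "params": {}}
            for f in range(5)
        ]
        return EvalReport(method, per_fold, seed, 5)

    def test_report_against_itself_gives_p_one(self):
        rep = self._report("naive", 0)
        other = self._report("copy", 0)
        table = compare_reports([rep, other], reference="naive")
        row = table[table.method == "copy"].iloc[0]
        assert row.p_aupr_vs_ref == 1.0 and row.p_auroc_vs_ref == 1.0

    def test_p_values_match_direct_calls(self):
        a, b = self._report("naive", 0), self._report("vkr", 0, shift=0.013)
        table = compare_reports([a, b], reference="naive")
        row = table[table.method == "vkr"].iloc[0]
        assert row.p_aupr_vs_ref == pytest.approx(
            paired_t_test(b.auprs, a.auprs)
        )

    def test_sum_metric_reported(self):
        table = compare_reports([self._report("naive", 0)])
        assert table.aupr_plus_auroc.iloc[0] == pytest.approx(
            table.mean_aupr.iloc[0] + table.mean_auroc.iloc[0]
        )

    def test_mismatched_seeds_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_reports([self._report("a", 0), self._report("b", 1)])

    def test_round_trip_through_directory(self, tmp_path):
        rep = nested_cv(
            NaiveSpec(),
            InteractionMatrix(
                (np.arange(40).reshape(5, 8) % 3 == 0).astype(int),
                [f"a{i}" for i in range(5)],
                [f"d{j}" for j in range(8)],
            ),
            HyperGrid(), outer=3, inner=2, seed=1,
        )
        rep.to_dir(tmp_path / "rep")
        back = EvalReport.from_dir(tmp_path / "rep")
        assert back.method == rep.method and back.seed == rep.seed
        np.testing.assert_allclose(back.auprs, rep.auprs)
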