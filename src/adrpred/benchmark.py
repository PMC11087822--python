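"""Reference experiments on the synthetic cold-start benchmark.

These are the package's standard end-to-end runs: generate the default
synthetic dataset, hold out 25% of drugs as new, tune each method by
5-fold CV on the known drugs (AUPR criterion, reduced grid), refit, and
score the hold-out micro-pooled.  They back both the test suite's
end-to-end checks and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

from .evaluation import HyperGrid, holdout_evaluate, nested_cv
from .models import make_predictor
from .synthetic import SyntheticSpec, benchmark_grid, planted_benchmark

__all__ = ["holdout_comparison", "nested_cv_comparison", "win_counts"]


def _predictor(method: str, bench):
    features = None if method == "naive" else [bench.X_all]
    return make_predictor(method, features)


def holdout_comparison(
    seed: int,
    methods: tuple[str, ...] = ("naive", "kr", "vkr"),
    spec: SyntheticSpec | None = None,
    grid: HyperGrid | None = None,
    tune_folds: int = 5,
) -> dict[str, dict]:
    """Tune-and-score every method on one seeded hold-out benchmark.

    Returns {method: {"aupr", "auroc", "params"}}.
    """
    spec = replace(spec or SyntheticSpec(), seed=seed)
    grid = grid or benchmark_grid()
    bench = planted_benchmark(spec)
    out: dict[str, dict] = {}
    for method in methods:
        out[method] = holdout_evaluate(
            _predictor(method, bench),
            bench.Y0,
            bench.split.new_drug_ids,
            grid,
            n_folds=tune_folds,
            seed=seed,
        )
    return out


def nested_cv_comparison(
    seed: int,
    methods: tuple[str, ...] = ("naive", "vkr"),
    spec: SyntheticSpec | None = None,
    grid: HyperGrid | None = None,
    outer: int = 5,
    inner: int = 4,
) -> dict[str, object]:
    """5×4 nested CV on the known drugs of one seeded benchmark.

    All methods share the seed, hence byte-identical fold plans, so their
    per-fold metrics are paired.  Returns {method: EvalReport}.
    """
    spec = replace(spec or SyntheticSpec(), seed=seed)
    grid = grid or benchmark_grid()
    bench = planted_benchmark(spec)
    return {
        method: nested_cv(
            _predictor(method, bench), bench.Y_known, grid,
            outer=outer, inner=inner, seed=seed,
        )
        for method in methods
    }


def win_counts(
    n_seeds: int = 10,
    base_seed: int = 0,
    spec: SyntheticSpec | None = None,
    grid: HyperGrid | None = None,
) -> dict[str, int]:
    """How often tuned VKR beats the naive baseline on the hold-out set.

    Runs ``holdout_comparison`` on ``n_seeds`` consecutive seeds and counts
    seeds where VKR's micro-AUROC (resp. micro-AUPR) strictly exceeds the
    naive baseline's.
    """
    auroc_wins = aupr_wins = 0
    for i in range(n_seeds):
        seed = (base_seed + i) % (2**31)
        res = holdout_comparison(seed, methods=("naive", "vkr"), spec=spec, grid=grid)
        auroc_wins += res["vkr"]["auroc"] > res["naive"]["auroc"]
        aupr_wins += res["vkr"]["aupr"] > res["naive"]["aupr"]
    return {"auroc_wins": auroc_wins, "aupr_wins": aupr_wins, "n_seeds": n_seeds}
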