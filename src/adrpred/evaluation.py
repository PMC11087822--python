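"""Ranking metrics and the cross-validation harness.

Metrics are micro-pooled: all (ADR, new-drug) entries of a fold are
flattened into one label/score vector before AUPR (average precision) and
AUROC are computed, giving a single value per fold.  This is the only
pooling under which a constant prevalence predictor can attain a high
AUROC, which is exactly why it is the relevant baseline regime for
severely imbalanced drug–ADR data.

The harness provides seeded balanced k-fold plans, grid search with an
inner CV, 5×4 nested cross-validation (hyperparameters tuned only inside
each outer-training set), hold-out evaluation, and paired t-tests across
folds.  Because fold plans depend only on the seed — never on the method —
different methods evaluated under the same seed see byte-identical folds,
the precondition for pairing the t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .matrixdata import InteractionMatrix, mask_new_drugs
from .models import PredictionMatrix, Predictor

__all__ = [
    "SingleClassError",
    "FoldPlan",
    "HyperGrid",
    "EvalReport",
    "aupr",
    "auroc",
    "pool_and_score",
    "make_folds",
    "cross_validate",
    "grid_search_cv",
    "nested_cv",
    "holdout_evaluate",
    "paired_t_test",
    "compare_reports",
]


class SingleClassError(ValueError):
    """Labels contain only one class; ranking metrics are undefined."""


def _validate_labels(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise SingleClassError("need at least one positive and one negative label")
    return labels, scores


def aupr(labels, scores) -> float:
    """Area under the precision–recall curve (average precision).

    Step-wise average precision: tied scores form one block and every item
    in the block receives the block-end precision.  Constant scores give
    the positive prevalence.
    """
    labels, scores = _validate_labels(labels, scores)
    return float(average_precision_score(labels, scores))


def auroc(labels, scores) -> float:
    """Area under the ROC curve — P(score+ > score-) + 0.5 P(score+ = score-)."""
    labels, scores = _validate_labels(labels, scores)
    return float(roc_auc_score(labels, scores))


def pool_and_score(
    Y_truth: InteractionMatrix, predictions: PredictionMatrix
) -> tuple[float, float]:
    """Micro-pooled (AUPR, AUROC) over all (ADR, new-drug) entries."""
    if Y_truth.adr_ids != predictions.adr_ids or Y_truth.drug_ids != predictions.drug_ids:
        raise ValueError("truth and prediction matrices are indexed differently")
    labels = np.asarray(Y_truth.values).ravel()
    scores = np.asarray(predictions.scores).ravel()
    return aupr(labels, scores), auroc(labels, scores)


@dataclass
class FoldPlan:
    """Seeded balanced partition of drugs into folds."""

    assignments: dict[str, int]
    n_folds: int
    seed: int

    def fold_drugs(self, fold: int) -> list[str]:
        return [d for d, f in self.assignments.items() if f == fold]

    def train_drugs(self, fold: int) -> list[str]:
        return [d for d, f in self.assignments.items() if f != fold]


def make_folds(drug_ids: Sequence[str], n_folds: int, seed: int) -> FoldPlan:
    """Uniform random balanced fold assignment, reproducible from the seed."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > len(drug_ids):
        raise ValueError("more folds than drugs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drug_ids))
    base, extra = divmod(len(drug_ids), n_folds)
    assignments: dict[str, int] = {}
    pos = 0
    for fold in range(n_folds):
        size = base + (1 if fold < extra else 0)
        for i in order[pos : pos + size]:
            assignments[drug_ids[i]] = fold
        pos += size
    # restore input drug order for stable iteration
    assignments = {d: assignments[d] for d in drug_ids}
    return FoldPlan(assignments, n_folds, seed)


_DEFAULT_LOG = tuple(float(10.0**e) for e in range(-3, 4))


@dataclass
class HyperGrid:
    """Hyperparameter grid: NMF rank L, ridge lambda, kernel width sigma, MKR mix."""

    n_components_values: tuple[int, ...] = (5, 10, 15, 20, 25)
    lambda_values: tuple[float, ...] = _DEFAULT_LOG
    sigma_values: tuple[float, ...] = _DEFAULT_LOG
    mix_values: tuple[float, ...] = (0.5,)


@dataclass
class EvalReport:
    """Per-fold metrics with chosen hyperparameters and summary statistics."""

    method: str
    per_fold: list[dict]  # {"fold", "aupr", "auroc", "params"}
    seed: int
    n_folds: int

    @property
    def auprs(self) -> np.ndarray:
        return np.array([f["aupr"] for f in self.per_fold])

    @property
    def aurocs(self) -> np.ndarray:
        return np.array([f["auroc"] for f in self.per_fold])

    @property
    def mean_aupr(self) -> float:
        return float(self.auprs.mean())

    @property
    def sd_aupr(self) -> float:
        return float(self.auprs.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def mean_auroc(self) -> float:
        return float(self.aurocs.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.aurocs.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.method}: AUPR {self.mean_aupr:.3f} ± {self.sd_aupr:.3f} (sd), "
            f"AUROC {self.mean_auroc:.3f} ± {self.sd_auroc:.3f} (sd) "
            f"over {len(self.per_fold)} folds (seed {self.seed})"
        )

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "fold": f["fold"],
                "aupr": f["aupr"],
                "auroc": f["auroc"],
                "params": ";".join(f"{k}={v}" for k, v in sorted(f["params"].items())),
            }
            for f in self.per_fold
        ]
        pd.DataFrame(rows).to_csv(path / "per_fold.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "method": self.method,
                    "seed": self.seed,
                    "n_folds": self.n_folds,
                    "mean_aupr": self.mean_aupr,
                    "sd_aupr": self.sd_aupr,
                    "mean_auroc": self.mean_auroc,
                    "sd_auroc": self.sd_auroc,
                }
            ]
        )
        summary.to_csv(path / "summary.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "EvalReport":
        path = Path(path)
        per_fold_df = pd.read_csv(path / "per_fold.tsv", sep="\t")
        summary = pd.read_csv(path / "summary.tsv", sep="\t").iloc[0]
        per_fold = []
        for _, row in per_fold_df.iterrows():
            params: dict = {}
            if isinstance(row.get("params"), str) and row["params"]:
                for item in row["params"].split(";"):
                    k, v = item.split("=", 1)
                    try:
                        params[k] = float(v) if "." in v or "e" in v.lower() else int(v)
                    except ValueError:
                        params[k] = v
            per_fold.append(
                {
                    "fold": int(row["fold"]),
                    "aupr": float(row["aupr"]),
                    "auroc": float(row["auroc"]),
                    "params": params,
                }
            )
        return cls(
            str(summary["method"]), per_fold, int(summary["seed"]), int(summary["n_folds"])
        )


def _evaluate_split(
    predictor: Predictor,
    Y: InteractionMatrix,
    val_drugs: Sequence[str],
    params: Mapping,
    seed: int,
) -> tuple[float, float]:
    """Mask validation drugs as new, fit on the rest, score micro-pooled."""
    Y_known, Y_truth = mask_new_drugs(Y, list(val_drugs))
    preds = predictor.fit_predict(Y_known, list(val_drugs), params, seed=seed)
    return pool_and_score(Y_truth, preds)


def cross_validate(
    predictor: Predictor,
    Y: InteractionMatrix,
    params: Mapping,
    n_folds: int,
    seed: int,
) -> EvalReport:
    """Plain k-fold CV at fixed hyperparameters (drugs masked as new per fold)."""
    plan = make_folds(Y.drug_ids, n_folds, seed)
    per_fold = []
    for fold in range(n_folds):
        a, r = _evaluate_split(
            predictor, Y, plan.fold_drugs(fold), params, _derive_seed(seed, fold)
        )
        per_fold.append({"fold": fold, "aupr": a, "auroc": r, "params": dict(params)})
    return EvalReport(predictor.name, per_fold, seed, n_folds)


def _derive_seed(seed: int, *parts: int) -> int:
    out = int(seed) % (2**31)
    for p in parts:
        out = (out * 1_000_003 + int(p) + 1) % (2**31)
    return out


def _tie_break_key(params: Mapping) -> tuple:
    """Prefer stronger regularization: larger lambda, smaller L, smaller sigma."""
    return (
        params.get("lam", 0.0),
        -params.get("n_components", 0),
        -params.get("sigma", 0.0),
        params.get("mix", 0.0),
    )


def grid_search_cv(
    predictor: Predictor,
    Y: InteractionMatrix,
    grid: HyperGrid,
    n_folds: int,
    seed: int,
    criterion: str = "aupr",
) -> tuple[dict, list[dict]]:
    """Select hyperparameters by mean micro-pooled AUPR over a k-fold CV.

    Folds with single-class pooled truth are skipped with a warning.
    Returns (best params, per-combination table).  Ties break toward
    stronger regularization (larger lambda, then smaller L, then smaller
    sigma) for determinism.
    """
    if criterion != "aupr":
        raise ValueError("the tuning criterion is AUPR")
    combos = predictor.iter_grid(grid)
    if not combos:
        raise ValueError("empty hyperparameter grid")
    # deduplicate while keeping order
    unique: list[dict] = []
    for c in combos:
        if c not in unique:
            unique.append(c)
    plan = make_folds(Y.drug_ids, n_folds, seed)
    table: list[dict] = []
    for params in unique:
        scores = []
        for fold in range(n_folds):
            try:
                a, _ = _evaluate_split(
                    predictor, Y, plan.fold_drugs(fold), params, _derive_seed(seed, fold)
                )
            except SingleClassError:
                warnings.warn(
                    f"fold {fold}: single-class pooled truth, skipped", stacklevel=2
                )
                continue
            scores.append(a)
        if not scores:
            raise SingleClassError("all folds degenerate; cannot tune")
        table.append({"params": params, "mean_aupr": float(np.mean(scores))})
    best = max(table, key=lambda r: (r["mean_aupr"],) + _tie_break_key(r["params"]))
    return dict(best["params"]), table


def nested_cv(
    predictor: Predictor,
    Y: InteractionMatrix,
    grid: HyperGrid,
    outer: int = 5,
    inner: int = 4,
    seed: int = 0,
) -> EvalReport:
    """Nested cross-validation: tune on inner folds, score on outer folds.

    For each outer fold, an inner ``inner``-fold grid search restricted to
    the outer-training drugs selects hyperparameters; the model is refit on
    the full outer-training set and scored (micro-pooled) on the outer
    validation drugs masked as new.  Fold plans depend only on the seed, so
    every method sees identical partitions.
    """
    plan = make_folds(Y.drug_ids, outer, seed)
    per_fold = []
    for fold in range(outer):
        train_ids = plan.train_drugs(fold)
        val_ids = plan.fold_drugs(fold)
        Y_train = Y.subset_drugs(train_ids)
        inner_seed = _derive_seed(seed, fold)
        best, _ = grid_search_cv(predictor, Y_train, grid, inner, inner_seed)
        a, r = _evaluate_split(predictor, Y, val_ids, best, _derive_seed(seed, fold, 7))
        per_fold.append({"fold": fold, "aupr": a, "auroc": r, "params": best})
    return EvalReport(predictor.name, per_fold, seed, outer)


def holdout_evaluate(
    predictor: Predictor,
    Y0: InteractionMatrix,
    new_drug_ids: Sequence[str],
    grid: HyperGrid,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Tune by CV on known drugs, refit on all of them, score the hold-out.

    Returns {"aupr", "auroc", "params"} for the hold-out drugs.
    """
    Y_known, Y_truth = mask_new_drugs(Y0, list(new_drug_ids))
    best, _ = grid_search_cv(predictor, Y_known, grid, n_folds, seed)
    preds = predictor.fit_predict(
        Y_known, list(new_drug_ids), best, seed=_derive_seed(seed, 99)
    )
    a, r = pool_and_score(Y_truth, preds)
    return {"aupr": a, "auroc": r, "params": best}


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on fold-wise metric differences."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length per-fold vectors of length >= 2")
    diffs = a - b
    if np.allclose(diffs, 0.0, atol=0.0):
        return 1.0
    if np.ptp(diffs) == 0.0:
        return 0.0  # identical nonzero shift on every fold: t = +-inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat = scipy.stats.ttest_rel(a, b)
    return float(stat.pvalue)


def compare_reports(reports: Sequence[EvalReport], reference: str | None = None) -> pd.DataFrame:
    """Method comparison table with paired t-tests against a reference.

    All reports must share the fold seed and fold count (otherwise the
    pairing across folds is invalid).  Adds the AUPR+AUROC sum as an
    overall score.
    """
    if not reports:
        raise ValueError("no reports to compare")
    seeds = {r.seed for r in reports}
    folds = {r.n_folds for r in reports}
    if len(seeds) > 1 or len(folds) > 1:
        raise ValueError("reports use different fold seeds or counts; unpaired")
    ref = None
    if reference is not None:
        matches = [r for r in reports if r.method == reference]
        if not matches:
            raise ValueError(f"reference method {reference!r} not among reports")
        ref = matches[0]
    rows = []
    for rep in reports:
        row = {
            "method": rep.method,
            "mean_aupr": rep.mean_aupr,
            "sd_aupr": rep.sd_aupr,
            "mean_auroc": rep.mean_auroc,
            "sd_auroc": rep.sd_auroc,
            "aupr_plus_auroc": rep.mean_aupr + rep.mean_auroc,
        }
        if ref is not None and len(reports) > 1:
            if rep is ref:
                row["p_aupr_vs_ref"] = np.nan
                row["p_auroc_vs_ref"] = np.nan
            else:
                row["p_aupr_vs_ref"] = paired_t_test(rep.auprs, ref.auprs)
                row["p_auroc_vs_ref"] = paired_t_test(rep.aurocs, ref.aurocs)
        rows.append(row)
    return pd.DataFrame(rows)
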