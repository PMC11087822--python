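"""Predictors for new-drug ADR profiles.

Four methods share a fit-on-known-drugs / predict-for-new-drugs contract,
all producing real-valued score matrices (ADR × new drug) that are ranked,
never thresholded:

* **naive** — each ADR's score for every new drug is that ADR's prevalence
  among the known drugs; no features used.
* **KR** — kernel ridge regression of the label matrix on a drug–drug RBF
  kernel: minimize ``||Y^T - K W||^2 + lambda ||W||^2`` and predict
  ``K_new W``.
* **VKR** — non-negative matrix factorization ``Y ~= U V^T`` de-noises the
  sparse label matrix, then kernel ridge regression maps drug features to
  the latent drug factor V; new-drug scores are ``U (K_new W)^T``.
* **MKR** — a convex combination of two single-kernel KR score matrices,
  one per feature source.

The ridge objective above is regularized on W with a Frobenius penalty and
solved in closed form, ``W = (K^T K + lambda I)^{-1} K^T T``.  The
classical RKHS variant ``W = (K + lambda I)^{-1} T`` is available behind
the ``rkhs`` flag for comparison.

The module offers both a functional layer (`kr_fit`, `nmf_factorize`, ...)
and model classes (`KernelRidgeADR(Y, features).fit(...)` returning a
results object with ``predict`` and ``summary``) built on top of it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .kernels import KernelMatrix, combine_kernels, rbf_kernel
from .matrixdata import FeatureTable, InteractionMatrix

__all__ = [
    "PredictionMatrix",
    "FactorPair",
    "CoefficientMatrix",
    "naive_fit_predict",
    "kr_fit",
    "kr_predict",
    "nmf_factorize",
    "vkr_fit",
    "vkr_predict",
    "mkr_fit_predict",
    "build_kernel",
    "NaiveADR",
    "KernelRidgeADR",
    "FactorizedKernelRidgeADR",
    "MultiKernelRidgeADR",
    "Predictor",
    "NaiveSpec",
    "KRSpec",
    "VKRSpec",
    "MKRSpec",
    "make_predictor",
]

_EPS = 1e-12  # zero-locking guard in multiplicative updates


# ---------------------------------------------------------------------------
# containers


@dataclass
class PredictionMatrix:
    """Real-valued ADR × new-drug score matrix."""

    scores: np.ndarray
    adr_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.adr_ids), len(self.drug_ids)):
            raise ValueError("score shape does not match id lists")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.scores, index=self.adr_ids, columns=self.drug_ids).to_csv(
            path, sep="\t", index_label="adr_id"
        )


@dataclass
class FactorPair:
    """Non-negative factors of ``Y ~= U V^T`` with the achieved objective."""

    U: np.ndarray  # M x L, ADR loadings
    V: np.ndarray  # N x L, drug loadings
    n_components: int
    objective: float
    n_iter: int
    seed: int
    history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def recomputed_objective(self, Y: np.ndarray) -> float:
        resid = np.asarray(Y, dtype=float) - self.U @ self.V.T
        return float(np.sum(resid**2))


@dataclass
class CoefficientMatrix:
    """Ridge coefficients W (training drugs × targets)."""

    W: np.ndarray
    lam: float
    rkhs: bool = False
    drug_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# functional layer


def naive_fit_predict(
    Y_known: InteractionMatrix, new_drug_ids: Sequence[str]
) -> PredictionMatrix:
    """Prevalence baseline: score(ADR i, any new drug) = mean_k Y_ik."""
    if Y_known.n_drugs == 0:
        raise ValueError("no known drugs")
    means = np.asarray(Y_known.values, dtype=float).mean(axis=1)
    scores = np.tile(means[:, None], (1, len(new_drug_ids)))
    return PredictionMatrix(scores, Y_known.adr_ids, list(new_drug_ids))


def _as_array(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def kr_fit(K, targets: np.ndarray, lam: float, rkhs: bool = False) -> CoefficientMatrix:
    """Closed-form ridge fit of ``targets`` (N × T) on a square kernel K.

    Minimizes ``||T - K W||^2 + lam ||W||^2`` via a stable linear solve of
    ``(K^T K + lam I) W = K^T T``; with ``rkhs=True`` solves
    ``(K + lam I) W = T`` instead.
    """
    Kv = _as_array(K)
    T = np.asarray(targets, dtype=float)
    if Kv.ndim != 2 or Kv.shape[0] != Kv.shape[1]:
        raise ValueError("K must be square")
    if T.ndim == 1:
        T = T[:, None]
    if T.shape[0] != Kv.shape[0]:
        raise ValueError("target rows must match kernel dimension")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n = Kv.shape[0]
    if rkhs:
        A = Kv + lam * np.eye(n)
        b = T
    else:
        A = Kv.T @ Kv + lam * np.eye(n)
        b = Kv.T @ T
    if lam == 0:
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError(
                "K^T K is singular at lambda = 0; use lambda > 0"
            )
        W = scipy.linalg.solve(A, b)
    else:
        W = scipy.linalg.solve(A, b, assume_a="pos")
    ids = list(K.ref_ids) if isinstance(K, KernelMatrix) else None
    return CoefficientMatrix(W, float(lam), rkhs, ids)


def kr_predict(K_new, W: CoefficientMatrix | np.ndarray) -> np.ndarray:
    """Ridge prediction ``K_new W`` (new drugs × targets)."""
    Kv = _as_array(K_new)
    Wv = W.W if isinstance(W, CoefficientMatrix) else np.asarray(W, dtype=float)
    if Kv.shape[1] != Wv.shape[0]:
        raise ValueError(
            f"kernel has {Kv.shape[1]} reference drugs but W has {Wv.shape[0]} rows"
        )
    return Kv @ Wv


def nmf_factorize(
    Y,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 1,
) -> FactorPair:
    """Frobenius NMF ``Y ~= U V^T`` by Lee–Seung multiplicative updates.

    U and V are initialized uniform-random non-negative and scaled so that
    ``mean(U V^T) = mean(Y)``; updates are guaranteed non-increasing in the
    squared-Frobenius objective (a 1e-12 additive guard in the denominators
    prevents zero-locking on sparse Y).  Iteration stops at ``max_iter`` or
    when the relative objective decrease falls below ``tol``.

    Multiplicative updates can stall on init-dependent plateaus; with
    ``n_restarts > 1`` the factorization is repeated from seeds derived
    deterministically from ``seed`` and the run with the lowest final
    objective is returned.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if n_restarts > 1:
        runs = [
            nmf_factorize(Y, n_components, seed=(seed + 7919 * r) % (2**31),
                          max_iter=max_iter, tol=tol)
            for r in range(n_restarts)
        ]
        best = min(runs, key=lambda f: f.objective)
        return best
    Yv = np.asarray(Y.values if isinstance(Y, InteractionMatrix) else Y, dtype=float)
    if (Yv < 0).any():
        raise ValueError("Y must be non-negative")
    M, N = Yv.shape
    L = int(n_components)
    if not 1 <= L <= min(M, N):
        raise ValueError(f"n_components must be in [1, {min(M, N)}], got {L}")
    rng = np.random.default_rng(seed)
    U = rng.uniform(size=(M, L))
    V = rng.uniform(size=(N, L))
    mean_y = Yv.mean()
    if mean_y == 0:
        zero_u, zero_v = np.zeros((M, L)), np.zeros((N, L))
        return FactorPair(zero_u, zero_v, L, 0.0, 0, seed, np.zeros(1))

    scale = np.sqrt(mean_y / (U @ V.T).mean())
    U *= scale
    V *= scale

    def objective(Umat: np.ndarray, Vmat: np.ndarray) -> float:
        return float(np.sum((Yv - Umat @ Vmat.T) ** 2))

    history = [objective(U, V)]
    for it in range(1, max_iter + 1):
        U *= (Yv @ V) / (U @ (V.T @ V) + _EPS)
        V *= (Yv.T @ U) / (V @ (U.T @ U) + _EPS)
        obj = objective(U, V)
        history.append(obj)
        prev = history[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return FactorPair(U, V, L, history[-1], len(history) - 1, seed, np.array(history))


def vkr_fit(
    Y_known: InteractionMatrix,
    K: KernelMatrix,
    n_components: int,
    lam: float,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    rkhs: bool = False,
) -> tuple[FactorPair, CoefficientMatrix]:
    """Factorize the known-drug label matrix, then ridge-fit the drug factor.

    The drug factor V (known drugs × L) is the regression target, so new
    drugs' latent coordinates can be predicted from their kernel rows.
    """
    factors = nmf_factorize(Y_known, n_components, seed=seed, max_iter=max_iter, tol=tol)
    coef = kr_fit(K, factors.V, lam, rkhs=rkhs)
    return factors, coef


def vkr_predict(
    U: np.ndarray,
    W: CoefficientMatrix | np.ndarray,
    K_new,
    adr_ids: list[str] | None = None,
    drug_ids: list[str] | None = None,
) -> PredictionMatrix:
    """Reconstruct new-drug ADR scores as ``U (K_new W)^T``."""
    V_new = kr_predict(K_new, W)  # N' x L
    U = np.asarray(U, dtype=float)
    if U.shape[1] != V_new.shape[1]:
        raise ValueError("U and K_new W have incompatible component counts")
    scores = U @ V_new.T
    if adr_ids is None:
        adr_ids = [f"adr{i}" for i in range(U.shape[0])]
    if drug_ids is None:
        if isinstance(K_new, KernelMatrix):
            drug_ids = list(K_new.query_ids)
        else:
            drug_ids = [f"new{i}" for i in range(V_new.shape[0])]
    return PredictionMatrix(scores, adr_ids, drug_ids)


def mkr_fit_predict(
    kernel_pairs: Sequence[tuple[KernelMatrix, KernelMatrix]],
    targets: np.ndarray,
    lambdas: Sequence[float],
    mix: float,
) -> np.ndarray:
    """Multiple-kernel ridge: convex combination of two per-kernel scores.

    ``score = mix * KR(K1, lam1) + (1 - mix) * KR(K2, lam2)``, each term fit
    and predicted independently on its own kernel pair (train, new).
    """
    if len(kernel_pairs) != 2 or len(lambdas) != 2:
        raise ValueError("MKR integrates exactly two kernels")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    preds = []
    for (K_train, K_new), lam in zip(kernel_pairs, lambdas):
        W = kr_fit(K_train, targets, lam)
        preds.append(kr_predict(K_new, W))
    return mix * preds[0] + (1.0 - mix) * preds[1]


def build_kernel(
    features: Sequence[FeatureTable],
    query_ids: Sequence[str],
    ref_ids: Sequence[str],
    sigma: float,
    weights: Sequence[float] | None = None,
) -> KernelMatrix:
    """RBF kernel between drug sets, combining feature sources equally.

    Each feature table contributes one RBF kernel at the shared width
    ``sigma``; multiple sources are averaged (or weighted) entrywise.
    """
    parts = [
        rbf_kernel(t.subset_drugs(list(query_ids)), t.subset_drugs(list(ref_ids)), sigma)
        for t in features
    ]
    if len(parts) == 1 and weights is None:
        return parts[0]
    return combine_kernels(parts, list(weights) if weights is not None else None)


# ---------------------------------------------------------------------------
# model classes


class _ResultsBase:
    """Shared summary plumbing for fitted ADR models."""

    method: str = ""

    def _summary_rows(self) -> list[tuple[str, str]]:
        return []

    def summary(self) -> str:
        rows = self._summary_rows()
        width = max((len(k) for k, _ in rows), default=10) + 2
        lines = [f"{self.method} results", "=" * 40]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)


class NaiveADR:
    """Prevalence baseline model over a known-drug label matrix."""

    def __init__(self, Y_known: InteractionMatrix):
        self.Y_known = Y_known

    def fit(self) -> "NaiveResults":
        means = np.asarray(self.Y_known.values, dtype=float).mean(axis=1)
        return NaiveResults(self, means)


@dataclass
class NaiveResults(_ResultsBase):
    model: NaiveADR
    prevalence: np.ndarray
    method: str = "naive"

    def predict(self, new_drug_ids: Sequence[str]) -> PredictionMatrix:
        return naive_fit_predict(self.model.Y_known, new_drug_ids)

    def _summary_rows(self):
        return [
            ("n ADRs", str(self.prevalence.size)),
            ("n known drugs", str(self.model.Y_known.n_drugs)),
            ("mean prevalence", f"{self.prevalence.mean():.4f}"),
        ]


class KernelRidgeADR:
    """Kernel ridge regression of the ADR label matrix on drug features."""

    def __init__(
        self,
        Y_known: InteractionMatrix,
        features: Sequence[FeatureTable],
        kernel_weights: Sequence[float] | None = None,
    ):
        if not features:
            raise ValueError("KR needs at least one feature table")
        self.Y_known = Y_known
        self.features = list(features)
        self.kernel_weights = kernel_weights

    def fit(self, lam: float, sigma: float, rkhs: bool = False) -> "KernelRidgeResults":
        ids = self.Y_known.drug_ids
        K = build_kernel(self.features, ids, ids, sigma, self.kernel_weights)
        targets = np.asarray(self.Y_known.values, dtype=float).T  # N x M
        coef = kr_fit(K, targets, lam, rkhs=rkhs)
        return KernelRidgeResults(self, coef, sigma)


@dataclass
class KernelRidgeResults(_ResultsBase):
    model: KernelRidgeADR
    coef: CoefficientMatrix
    sigma: float
    method: str = "kr"

    def predict(self, X_new_ids: Sequence[str] | None = None) -> PredictionMatrix:
        """Score new drugs identified by id within the model's feature tables."""
        if X_new_ids is None:
            raise ValueError("new drug ids required")
        K_new = build_kernel(
            self.model.features,
            X_new_ids,
            self.model.Y_known.drug_ids,
            self.sigma,
            self.model.kernel_weights,
        )
        scores = kr_predict(K_new, self.coef).T  # M x N'
        return PredictionMatrix(scores, self.model.Y_known.adr_ids, list(X_new_ids))

    def _summary_rows(self):
        return [
            ("lambda", f"{self.coef.lam:g}"),
            ("sigma", f"{self.sigma:g}"),
            ("form", "rkhs" if self.coef.rkhs else "objective"),
            ("n training drugs", str(self.model.Y_known.n_drugs)),
            ("features", "+".join(t.name for t in self.model.features)),
        ]


class FactorizedKernelRidgeADR:
    """VKR: NMF de-noising of Y followed by kernel ridge on the drug factor."""

    def __init__(
        self,
        Y_known: InteractionMatrix,
        features: Sequence[FeatureTable],
        kernel_weights: Sequence[float] | None = None,
    ):
        if not features:
            raise ValueError("VKR needs at least one feature table")
        self.Y_known = Y_known
        self.features = list(features)
        self.kernel_weights = kernel_weights

    def fit(
        self,
        n_components: int,
        lam: float,
        sigma: float,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-6,
        rkhs: bool = False,
    ) -> "FactorizedKernelRidgeResults":
        ids = self.Y_known.drug_ids
        K = build_kernel(self.features, ids, ids, sigma, self.kernel_weights)
        factors, coef = vkr_fit(
            self.Y_known, K, n_components, lam, seed=seed, max_iter=max_iter,
            tol=tol, rkhs=rkhs,
        )
        return FactorizedKernelRidgeResults(self, factors, coef, sigma)


@dataclass
class FactorizedKernelRidgeResults(_ResultsBase):
    model: FactorizedKernelRidgeADR
    factors: FactorPair
    coef: CoefficientMatrix
    sigma: float
    method: str = "vkr"

    def predict(self, X_new_ids: Sequence[str]) -> PredictionMatrix:
        K_new = build_kernel(
            self.model.features,
            X_new_ids,
            self.model.Y_known.drug_ids,
            self.sigma,
            self.model.kernel_weights,
        )
        return vkr_predict(
            self.factors.U,
            self.coef,
            K_new,
            adr_ids=self.model.Y_known.adr_ids,
            drug_ids=list(X_new_ids),
        )

    def _summary_rows(self):
        return [
            ("n components", str(self.factors.n_components)),
            ("lambda", f"{self.coef.lam:g}"),
            ("sigma", f"{self.sigma:g}"),
            ("NMF objective", f"{self.factors.objective:.6g}"),
            ("NMF iterations", str(self.factors.n_iter)),
            ("n training drugs", str(self.model.Y_known.n_drugs)),
            ("features", "+".join(t.name for t in self.model.features)),
        ]


class MultiKernelRidgeADR:
    """MKR: convex combination of two single-feature KR score matrices."""

    def __init__(self, Y_known: InteractionMatrix, features: Sequence[FeatureTable]):
        if len(features) != 2:
            raise ValueError("MKR requires exactly two feature tables")
        self.Y_known = Y_known
        self.features = list(features)

    def fit(
        self, lam: float, sigma: float, mix: float = 0.5,
        lam2: float | None = None, sigma2: float | None = None,
    ) -> "MultiKernelRidgeResults":
        if not 0.0 <= mix <= 1.0:
            raise ValueError("mix must lie in [0, 1]")
        return MultiKernelRidgeResults(
            self, lam, lam2 if lam2 is not None else lam,
            sigma, sigma2 if sigma2 is not None else sigma, mix,
        )


@dataclass
class MultiKernelRidgeResults(_ResultsBase):
    model: MultiKernelRidgeADR
    lam1: float
    lam2: float
    sigma1: float
    sigma2: float
    mix: float
    method: str = "mkr"

    def predict(self, X_new_ids: Sequence[str]) -> PredictionMatrix:
        Y = self.model.Y_known
        targets = np.asarray(Y.values, dtype=float).T
        pairs = []
        for table, sig in zip(self.model.features, (self.sigma1, self.sigma2)):
            K = build_kernel([table], Y.drug_ids, Y.drug_ids, sig)
            K_new = build_kernel([table], X_new_ids, Y.drug_ids, sig)
            pairs.append((K, K_new))
        scores = mkr_fit_predict(pairs, targets, (self.lam1, self.lam2), self.mix).T
        return PredictionMatrix(scores, Y.adr_ids, list(X_new_ids))

    def _summary_rows(self):
        return [
            ("lambda (k1, k2)", f"{self.lam1:g}, {self.lam2:g}"),
            ("sigma (k1, k2)", f"{self.sigma1:g}, {self.sigma2:g}"),
            ("mix", f"{self.mix:g}"),
            ("features", "+".join(t.name for t in self.model.features)),
        ]


# ---------------------------------------------------------------------------
# predictor specs for the evaluation harness


class Predictor:
    """Uniform fit/predict interface the CV harness drives.

    A predictor owns its feature tables (defined over the full drug
    universe) and is handed only known-drug labels plus the identities of
    the drugs to score; subclasses enumerate their hyperparameter grid.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, features: Sequence[FeatureTable] | None = None):
        self.features = list(features) if features else []

    def iter_grid(self, grid) -> list[dict]:
        raise NotImplementedError

    def fit_predict(
        self,
        Y_known: InteractionMatrix,
        new_drug_ids: Sequence[str],
        params: Mapping,
        seed: int = 0,
    ) -> PredictionMatrix:
        raise NotImplementedError


class NaiveSpec(Predictor):
    name = "naive"
    param_names = ()

    def iter_grid(self, grid) -> list[dict]:
        return [{}]

    def fit_predict(self, Y_known, new_drug_ids, params, seed=0):
        return NaiveADR(Y_known).fit().predict(new_drug_ids)


class KRSpec(Predictor):
    name = "kr"
    param_names = ("lam", "sigma")

    def __init__(self, features, rkhs: bool = False, kernel_weights=None):
        super().__init__(features)
        self.rkhs = rkhs
        self.kernel_weights = kernel_weights

    def iter_grid(self, grid) -> list[dict]:
        return [
            {"lam": lam, "sigma": sig}
            for lam, sig in itertools.product(
                sorted(grid.lambda_values), sorted(grid.sigma_values)
            )
        ]

    def fit_predict(self, Y_known, new_drug_ids, params, seed=0):
        model = KernelRidgeADR(Y_known, self.features, self.kernel_weights)
        res = model.fit(params["lam"], params["sigma"], rkhs=self.rkhs)
        return res.predict(new_drug_ids)


class VKRSpec(Predictor):
    name = "vkr"
    param_names = ("n_components", "lam", "sigma")

    def __init__(self, features, rkhs: bool = False, kernel_weights=None,
                 max_iter: int = 500, tol: float = 1e-6):
        super().__init__(features)
        self.rkhs = rkhs
        self.kernel_weights = kernel_weights
        self.max_iter = max_iter
        self.tol = tol

    def iter_grid(self, grid) -> list[dict]:
        return [
            {"n_components": L, "lam": lam, "sigma": sig}
            for L, lam, sig in itertools.product(
                sorted(grid.n_components_values),
                sorted(grid.lambda_values),
                sorted(grid.sigma_values),
            )
        ]

    def fit_predict(self, Y_known, new_drug_ids, params, seed=0):
        model = FactorizedKernelRidgeADR(Y_known, self.features, self.kernel_weights)
        L = min(params["n_components"], Y_known.n_drugs, Y_known.n_adrs)
        res = model.fit(
            L, params["lam"], params["sigma"], seed=seed,
            max_iter=self.max_iter, tol=self.tol, rkhs=self.rkhs,
        )
        return res.predict(new_drug_ids)


class MKRSpec(Predictor):
    name = "mkr"
    param_names = ("lam", "sigma", "mix")

    def iter_grid(self, grid) -> list[dict]:
        mixes = grid.mix_values or (0.5,)
        return [
            {"lam": lam, "sigma": sig, "mix": mix}
            for lam, sig, mix in itertools.product(
                sorted(grid.lambda_values), sorted(grid.sigma_values), sorted(mixes)
            )
        ]

    def fit_predict(self, Y_known, new_drug_ids, params, seed=0):
        model = MultiKernelRidgeADR(Y_known, self.features)
        res = model.fit(params["lam"], params["sigma"], mix=params["mix"])
        return res.predict(new_drug_ids)


def make_predictor(
    method: str, features: Sequence[FeatureTable] | None = None, **kwargs
) -> Predictor:
    """Build a predictor spec by method name ('naive', 'kr', 'vkr', 'mkr')."""
    registry = {"naive": NaiveSpec, "kr": KRSpec, "vkr": VKRSpec, "mkr": MKRSpec}
    if method not in registry:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(registry)}")
    if method == "naive":
        return NaiveSpec()
    return registry[method](features, **kwargs)
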