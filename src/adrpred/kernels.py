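"""Gaussian RBF drug–drug kernels over binary feature vectors.

The similarity between drugs i and j with feature vectors x_i, x_j is

    k(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2)),

so entries lie in (0, 1] with unit self-similarity.  Multiple feature
sources (e.g. drug–gene interaction bits and chemical fingerprints) are
integrated as a convex combination of their kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

from .matrixdata import FeatureTable

__all__ = ["KernelMatrix", "rbf_kernel", "combine_kernels"]


@dataclass
class KernelMatrix:
    """Real-valued drug–drug similarity matrix, rows = query drugs."""

    values: np.ndarray
    query_ids: list[str]
    ref_ids: list[str]
    sigma: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.query_ids = list(self.query_ids)
        self.ref_ids = list(self.ref_ids)
        if self.values.shape != (len(self.query_ids), len(self.ref_ids)):
            raise ValueError("kernel shape does not match id lists")

    @property
    def is_square(self) -> bool:
        return self.query_ids == self.ref_ids


def rbf_kernel(X_query: FeatureTable, X_ref: FeatureTable, sigma: float) -> KernelMatrix:
    """RBF kernel between query and reference drugs in a shared feature space."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if X_query.feature_ids != X_ref.feature_ids:
        raise ValueError("query and reference feature spaces differ")
    gamma = 1.0 / (2.0 * sigma**2)
    values = _sk_rbf(
        np.asarray(X_query.values, dtype=float),
        np.asarray(X_ref.values, dtype=float),
        gamma=gamma,
    )
    if X_query.drug_ids == X_ref.drug_ids:
        # enforce exact symmetry / unit diagonal against float round-off
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
    return KernelMatrix(
        values, X_query.drug_ids, X_ref.drug_ids, sigma=sigma, source=X_query.name
    )


def combine_kernels(
    kernels: list[KernelMatrix], weights: list[float] | None = None
) -> KernelMatrix:
    """Convex combination of kernels sharing identical drug orderings.

    Weights are normalized to sum to one, which preserves the unit diagonal
    of RBF kernels and makes the combination scale-free.
    """
    if not kernels:
        raise ValueError("need at least one kernel")
    if weights is None:
        weights = [1.0] * len(kernels)
    if len(weights) != len(kernels):
        raise ValueError("one weight per kernel required")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    w = w / total
    first = kernels[0]
    for k in kernels[1:]:
        if k.query_ids != first.query_ids or k.ref_ids != first.ref_ids:
            raise ValueError("kernels are indexed by different drug orderings")
    values = sum(wi * k.values for wi, k in zip(w, kernels))
    source = "+".join(k.source for k in kernels if k.source)
    return KernelMatrix(values, first.query_ids, first.ref_ids, sigma=None, source=source)
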