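"""Seeded synthetic drug–ADR data with the structure the method assumes.

The generator emulates three statistical properties of real
pharmacovigilance label data:

* extreme sparsity — by default ~2.4% of (ADR, drug) entries are positive;
* approximately low-rank structure — positives arise from a non-negative
  latent factor model ``P ∝ U* V*^T`` with right-skewed (gamma) factors,
  so a few components dominate and ADR prevalence is heavily skewed,
  which is what makes the prevalence baseline nontrivially strong;
* feature relevance — binary drug features (think DGI bits or fingerprint
  bits) are Bernoulli draws whose per-drug rates are monotone functions of
  the latent drug factors, blended with pure noise by an
  ``feature_informativeness`` dial in [0, 1].

It does not emulate MedDRA term structure, drug classes, or real
chemistry; it exists so the full pipeline (masking, kernels, models,
nested CV) can be exercised end to end without any external downloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .matrixdata import FeatureTable, InteractionMatrix, SplitPlan, mask_new_drugs, split_holdout
from .models import FactorPair

__all__ = [
    "SyntheticSpec",
    "Benchmark",
    "generate",
    "planted_benchmark",
    "benchmark_grid",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration (defaults are the package's study conditions)."""

    M: int = 200  # ADR count
    N: int = 150  # drug count
    L_true: int = 5  # latent rank
    p: int = 300  # feature count
    target_density: float = 0.0244  # expected fraction of positive entries
    feature_informativeness: float = 0.8
    noise_flip_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.L_true <= min(self.M, self.N):
            raise ValueError("L_true must be in [1, min(M, N)]")
        if not 0 < self.target_density < 1:
            raise ValueError("target_density must be in (0, 1)")
        if not 0 <= self.feature_informativeness <= 1:
            raise ValueError("feature_informativeness must be in [0, 1]")
        if not 0 <= self.noise_flip_rate < 1:
            raise ValueError("noise_flip_rate must be in [0, 1)")


def generate(spec: SyntheticSpec) -> tuple[InteractionMatrix, FeatureTable, FactorPair]:
    """Draw (Y, X, ground-truth factors) from the latent factor model.

    Positives: ``P = c · U* V*^T`` clipped to [0, 1] with c chosen so that
    ``mean(P) = target_density``; ``Y_ij ~ Bernoulli(P_ij)`` with each
    entry then flipped independently at ``noise_flip_rate``.  Features:
    bit f of drug j is Bernoulli with rate
    ``informativeness · g_f(V*_j) + (1 - informativeness) · q_f`` where
    ``g_f`` is a random logistic ramp in one latent component and ``q_f``
    a random base rate.  The returned ground-truth factors are for
    recovery diagnostics only and must never reach a model path.
    """
    rng = np.random.default_rng(spec.seed)
    # right-skewed non-negative factors: a few components dominate
    U_star = rng.gamma(shape=0.5, scale=1.0, size=(spec.M, spec.L_true))
    V_star = rng.gamma(shape=0.5, scale=1.0, size=(spec.N, spec.L_true))
    P = U_star @ V_star.T
    P *= spec.target_density / P.mean()
    clipped = P > 1.0
    P = np.clip(P, 0.0, 1.0)
    if clipped.any() and abs(P.mean() - spec.target_density) > 0.1 * spec.target_density:
        warnings.warn(
            f"clipping moved realized density to {P.mean():.4f} "
            f"(target {spec.target_density})",
            stacklevel=2,
        )
    Y = (rng.uniform(size=P.shape) < P).astype(np.int8)
    if spec.noise_flip_rate > 0:
        flips = rng.uniform(size=Y.shape) < spec.noise_flip_rate
        Y = np.where(flips, 1 - Y, Y).astype(np.int8)

    # binary features: per-drug Bernoulli rates monotone in one latent component
    comp = rng.integers(0, spec.L_true, size=spec.p)
    slope = rng.uniform(0.5, 2.0, size=spec.p) * rng.choice((-1.0, 1.0), size=spec.p)
    offset = rng.normal(size=spec.p)
    base_rate = rng.uniform(0.1, 0.5, size=spec.p)
    Vz = (V_star - V_star.mean(axis=0)) / (V_star.std(axis=0) + 1e-12)
    ramp = 1.0 / (1.0 + np.exp(-(Vz[:, comp] * slope + offset)))  # N x p
    rate = spec.feature_informativeness * ramp + (1 - spec.feature_informativeness) * base_rate
    X = (rng.uniform(size=(spec.N, spec.p)) < rate).astype(np.int8)

    adr_ids = [f"ADR{i:04d}" for i in range(spec.M)]
    drug_ids = [f"D{j:04d}" for j in range(spec.N)]
    feat_ids = [f"F{f:04d}" for f in range(spec.p)]
    Y_mat = InteractionMatrix(Y, adr_ids, drug_ids)
    X_tab = FeatureTable(X, drug_ids, feat_ids, name="synthetic")
    truth = FactorPair(
        U_star, V_star, spec.L_true,
        objective=float(np.sum((Y - U_star @ V_star.T) ** 2)),
        n_iter=0, seed=spec.seed,
    )
    return Y_mat, X_tab, truth


def benchmark_grid():
    """Reduced tuning grid used with the default synthetic benchmark.

    Covers the regularization/width/rank ranges that matter at the default
    problem size (binary features, p = 300, squared distances of order
    tens) while keeping a full tuning run to 18 combinations.
    """
    from .evaluation import HyperGrid

    return HyperGrid(
        n_components_values=(5, 10),
        lambda_values=(0.1, 1.0, 10.0),
        sigma_values=(3.0, 10.0, 30.0),
        mix_values=(0.5,),
    )


@dataclass
class Benchmark:
    """A masked cold-start benchmark: train on known drugs, score the new ones.

    Exposes only observable data (labels and features) — the generator's
    ground-truth factors are deliberately absent.
    """

    Y_known: InteractionMatrix
    Y_truth_new: InteractionMatrix
    X_known: FeatureTable
    X_new: FeatureTable
    split: SplitPlan
    Y0: InteractionMatrix
    X_all: FeatureTable


def planted_benchmark(spec: SyntheticSpec, holdout_fraction: float = 0.25) -> Benchmark:
    """Generate a dataset and mask a random drug fraction as new drugs."""
    if spec.N < 20:
        raise ValueError("need at least 20 drugs for a meaningful benchmark")
    Y0, X, _ = generate(spec)
    split = split_holdout(Y0.drug_ids, holdout_fraction, spec.seed)
    Y_known, Y_truth_new = mask_new_drugs(Y0, split.new_drug_ids)
    return Benchmark(
        Y_known=Y_known,
        Y_truth_new=Y_truth_new,
        X_known=X.subset_drugs(split.known_drug_ids),
        X_new=X.subset_drugs(split.new_drug_ids),
        split=split,
        Y0=Y0,
        X_all=X,
    )
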