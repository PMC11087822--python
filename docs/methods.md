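# Methods

## Problem setting

The label data are a binary matrix Y (M ADRs × N drugs); a "new" drug is
one whose label column is entirely unknown at training time (cold start).
New drugs are simulated by masking: the held-out drugs' columns are
removed from the training matrix entirely — no masked column ever reaches
a model — and kept aside as scoring truth. Features are binary per-drug
vectors (drug–gene interaction memberships, fingerprint bits); a drug
whose feature rows are absent or all-zero in every table is dropped,
because an all-zero vector carries no similarity information under an RBF
distance beyond a constant offset.

## Models

**Naive.** score(i, ·) = mean of row i of the known-drug Y. Constant
across drugs per ADR; under micro-pooling this ranks entries purely by
ADR prevalence, which on heavily skewed label data is a strong AUROC
baseline and the reference all feature-based methods must beat.

**Kernel ridge (KR).** With kernel K_ij = exp(−‖x_i−x_j‖²/2σ²), the
coefficients minimize ‖Yᵀ − K W‖² + λ‖W‖². We implement this objective
literally, giving the closed form W = (KᵀK + λI)⁻¹KᵀYᵀ via a
Cholesky-backed solve (never an explicit inverse). The classical RKHS
variant W = (K + λI)⁻¹Yᵀ is available behind an `rkhs` flag for
comparison; the two differ numerically but share limits and ranking
behavior on these data. λ = 0 is allowed only when KᵀK is well
conditioned (condition number ≤ 1e12); otherwise the fit raises and
advises λ > 0.

**VKR.** NMF first: minimize ‖Y − U Vᵀ‖² with U, V ≥ 0 by Lee–Seung
multiplicative updates. Initialization is uniform-random non-negative,
scaled so mean(U Vᵀ) = mean(Y); denominators carry a 1e-12 additive guard
against zero-locking on sparse Y; the objective is recorded every
iteration and is non-increasing by construction. Then the drug factor V
(not Y) is the ridge target: W = (KᵀK + λI)⁻¹KᵀV, and new-drug scores are
U (K_new W)ᵀ. An all-zero Y short-circuits to zero factors with objective
exactly 0.

Multiplicative updates can stall on init-dependent plateaus (observed on
planted exact-rank problems); `nmf_factorize(..., n_restarts=k)` reruns
from seeds derived deterministically from the given seed and keeps the
lowest final objective. Defaults: max_iter = 500, tol = 1e-6 relative
objective decrease, n_restarts = 1 (restarts are used where exact
convergence matters, e.g. planted-recovery checks).

**MKR.** Two feature sources, two kernels, two independent KR fits; the
final score is mix·s₁ + (1−mix)·s₂ with mix ∈ [0, 1] (default 0.5,
tunable).

**Feature integration for KR/VKR.** Multiple feature tables are combined
as a convex combination of their RBF kernels with weights normalized to
sum to one (this preserves the unit diagonal and decouples σ from weight
scale). Default weights are equal. A single σ is shared by all feature
kernels within one hyperparameter combination; tuning one σ per source
would square the σ axis of the grid for little benefit at these problem
sizes, and the shared axis keeps single- and multi-feature runs
comparable.

A note on the kernel: the Gaussian RBF is used with the standard negative
exponent. Scores are never thresholded or calibrated — all evaluation is
by ranking metrics.

## Evaluation protocol

Metrics are micro-pooled: all (ADR, new-drug) entries of a fold are
flattened into one vector before computing AUPR and AUROC, one value of
each per fold. Micro-pooling is the only convention under which a
constant per-ADR predictor has a meaningful (and high) AUROC, so it is
applied identically to every method. AUPR is step-wise average precision
(tied scores form one block scored at the block-end precision), not
trapezoidal interpolation, which over-estimates PR area. AUROC is the
rank statistic P(s⁺ > s⁻) + ½P(s⁺ = s⁻).

Cross-validation plans are balanced random partitions (fold sizes differ
by at most one) drawn from a seed. Nested CV (default 5 outer × 4 inner)
tunes hyperparameters by mean inner-fold AUPR only — AUPR is the tuning
criterion because it is the metric that the class imbalance makes hard —
then refits on the full outer-training set and scores the outer fold.
Fold plans depend only on the seed, never the method, so methods run
under one seed see byte-identical partitions; that pairing is what makes
fold-wise paired t-tests valid. Hold-out evaluation mirrors the protocol:
25% of drugs (round-half-up) are reserved before any model development,
hyperparameters come from a plain 5-fold CV on the known drugs, and the
hold-out is scored once.

Grid-search ties break deterministically toward stronger regularization:
larger λ, then smaller L, then smaller σ, then larger mix. Degenerate
validation folds whose pooled truth is single-class are skipped with a
warning; if all folds degenerate, tuning raises. The paired t-test
returns p = 1 when all fold differences are exactly zero and p = 0 when
they are a constant nonzero shift (zero variance, infinite t).

Default grids: λ and σ over 10⁻³…10³ (7 log-spaced values each),
L ∈ {5, 10, 15, 20, 25}, mix ∈ {0.5}.

## Synthetic benchmark

The generator draws non-negative latent factors U* (M×L_true), V*
(N×L_true) from a right-skewed gamma(0.5, 1) so a few components
dominate, mimicking real ADR prevalence skew; scales P = U*V*ᵀ so
mean(P) equals the target density; draws Y ~ Bernoulli(P); and flips each
entry independently at the noise rate. Feature bit f of drug j is
Bernoulli with rate informativeness·g_f(V*_j) + (1−informativeness)·q_f,
where g_f is a random-slope logistic ramp in one latent component and q_f
a random base rate — so feature-space similarity is correlated with
latent-space similarity exactly to the degree the informativeness dial
sets, and is independent of it at 0.

Defaults: M = 200 ADRs, N = 150 drugs, L_true = 5, p = 300 features,
target density 0.0244, informativeness 0.8, flip rate 0.02, 25% hold-out.
These sizes run in seconds while staying in the heavy-imbalance regime.
The density target applies to the Bernoulli layer; the 2% flips then
raise realized density to ≈0.043 and, because flipped positives are
unpredictable in principle, cap the attainable AUPR/AUROC well below
what real label data allow. Passing benchmarks here demonstrates that the
pipeline recovers plantable structure without leakage — not that any
particular absolute metric level transfers to real pharmacovigilance
data, which have MedDRA term structure, drug-class clustering, and
reporting biases the generator deliberately omits.

The benchmark experiments (`adrpred.benchmark`) tune on a reduced grid —
L ∈ {5, 10}, λ ∈ {0.1, 1, 10}, σ ∈ {3, 10, 30} — chosen to bracket the
scales relevant for binary features with p = 300 (typical squared
Hamming distances of order tens, hence σ of order 3–30) while keeping a
full tuning run at 18 combinations.

## Numerical choices and limitations

* Ridge solves use `scipy.linalg.solve` with the positive-definite path
  when λ > 0; kernels are symmetrized and given an exact unit diagonal to
  cancel float round-off.
* NMF determinism: all randomness flows through `numpy.random.default_rng`
  on an explicit seed; identical seeds give bit-identical factors,
  coefficients, splits and folds.
* Derived seeds (per fold, per restart) are computed by a fixed integer
  recurrence kept below 2³¹.
* The NMF rank is capped at min(M, N) of the training matrix actually
  being factorized, so a grid rank that exceeds a small inner-fold
  training set is clamped rather than failing.
* Known limitations: no identifier mapping between vocabularies (CID,
  drug names, gene symbols); no Tanimoto/Jaccard kernels; no per-ADR
  (macro) metrics; no calibration of scores to probabilities; NMF
  solutions are non-unique (rotations/permutations of factors), which is
  irrelevant to prediction but means U and V themselves are not
  interpretable without further constraints.
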