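"""Binary drug–ADR and drug–feature matrices: I/O, assembly, filtering, splitting.

Orientation conventions used throughout the package:

* the label matrix ``Y`` is ADR × drug (one column per drug, one row per
  adverse reaction),
* a feature table ``X`` is drug × feature (one row per drug).

Input files are flat tab-separated pair lists in the style of SIDER /
DGIdb exports: one ``drug<TAB>item`` pair per line, ``#`` comments
ignored, UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "FeatureTable",
    "SplitPlan",
    "PairListError",
    "read_pair_list",
    "read_fingerprint_table",
    "build_matrix",
    "build_interaction_matrix",
    "build_feature_table",
    "filter_featureless_drugs",
    "split_holdout",
    "mask_new_drugs",
]


class PairListError(ValueError):
    """Raised for malformed pair-list files."""


def _check_binary(values: np.ndarray) -> None:
    if not np.isin(values, (0, 1)).all():
        raise ValueError("matrix entries must be 0 or 1")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class InteractionMatrix:
    """Binary ADR × drug label matrix with aligned identifier lists."""

    values: np.ndarray
    adr_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        _check_binary(self.values)
        self.values = self.values.astype(np.int8)
        self.adr_ids = list(self.adr_ids)
        self.drug_ids = list(self.drug_ids)
        _check_unique(self.adr_ids, "ADR")
        _check_unique(self.drug_ids, "drug")
        if self.values.shape != (len(self.adr_ids), len(self.drug_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.adr_ids)} ADRs x {len(self.drug_ids)} drugs"
            )

    @property
    def n_adrs(self) -> int:
        return len(self.adr_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def density(self) -> float:
        """Fraction of positive entries."""
        return float(self.values.mean()) if self.values.size else 0.0

    def subset_drugs(self, drug_ids: list[str]) -> "InteractionMatrix":
        """Column subset in the given order; unknown ids raise KeyError."""
        idx = _indices(self.drug_ids, drug_ids, "drug")
        return InteractionMatrix(self.values[:, idx], self.adr_ids, list(drug_ids))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.adr_ids, columns=self.drug_ids).to_csv(
            path, sep="\t", index_label="adr_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class FeatureTable:
    """Binary drug × feature matrix (DGI bits, fingerprint bits, ...)."""

    values: np.ndarray
    drug_ids: list[str]
    feature_ids: list[str]
    name: str = "feature"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        _check_binary(self.values)
        self.values = self.values.astype(np.int8)
        self.drug_ids = list(self.drug_ids)
        self.feature_ids = list(self.feature_ids)
        _check_unique(self.drug_ids, "drug")
        if self.values.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_drugs(self, drug_ids: list[str]) -> "FeatureTable":
        idx = _indices(self.drug_ids, drug_ids, "drug")
        return FeatureTable(self.values[idx, :], list(drug_ids), self.feature_ids, self.name)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.drug_ids, columns=self.feature_ids).to_csv(
            path, sep="\t", index_label="drug_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "feature") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns], name
        )


@dataclass
class SplitPlan:
    """A known/new partition of the drug set (hold-out or CV masking)."""

    known_drug_ids: list[str]
    new_drug_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        known, new = set(self.known_drug_ids), set(self.new_drug_ids)
        if known & new:
            raise ValueError("known and new drug sets overlap")

    @property
    def all_drug_ids(self) -> list[str]:
        return list(self.known_drug_ids) + list(self.new_drug_ids)

    def to_tsv(self, path: str | Path) -> None:
        rows = [("known", d) for d in self.known_drug_ids] + [
            ("new", d) for d in self.new_drug_ids
        ]
        df = pd.DataFrame(rows, columns=["role", "drug_id"])
        df.attrs["seed"] = self.seed
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# seed={self.seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SplitPlan":
        seed = 0
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("# seed="):
                seed = int(first.strip().split("=", 1)[1])
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", comment="#")
        known = [str(d) for d in df.loc[df["role"] == "known", "drug_id"]]
        new = [str(d) for d in df.loc[df["role"] == "new", "drug_id"]]
        return cls(known, new, seed)


def _indices(universe: list[str], wanted: list[str], what: str) -> np.ndarray:
    lookup = {d: i for i, d in enumerate(universe)}
    missing = [d for d in wanted if d not in lookup]
    if missing:
        raise KeyError(f"unknown {what} ids: {missing}")
    return np.array([lookup[d] for d in wanted], dtype=np.intp)


def read_pair_list(path: str | Path, role: str = "adr") -> list[tuple[str, str]]:
    """Read a tab-separated (drug, item) pair list.

    Lines starting with ``#`` and blank lines are skipped; the first two
    tab-separated fields of every other line are taken as (drug, item).
    Pairs are deduplicated keeping first-occurrence order.
    """
    if role not in ("adr", "feature"):
        raise ValueError(f"role must be 'adr' or 'feature', got {role!r}")
    seen: dict[tuple[str, str], None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise PairListError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields"
                )
            seen.setdefault((fields[0].strip(), fields[1].strip()))
    return list(seen)


def read_fingerprint_table(path: str | Path, name: str = "Chem") -> FeatureTable:
    """Read a fingerprint file: drug id + a 0/1 string or comma-separated bits."""
    rows: list[np.ndarray] = []
    drugs: list[str] = []
    width: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise PairListError(f"{path}: line {lineno}: expected drug id + bits")
            bitstr = fields[1].strip()
            if "," in bitstr:
                bits = np.array([int(b) for b in bitstr.split(",")], dtype=np.int8)
            else:
                bits = np.array([int(c) for c in bitstr], dtype=np.int8)
            if width is None:
                width = bits.size
            elif bits.size != width:
                raise PairListError(
                    f"{path}: line {lineno}: fingerprint length {bits.size} != {width}"
                )
            drugs.append(fields[0].strip())
            rows.append(bits)
    if not rows:
        return FeatureTable(np.zeros((0, 0), dtype=np.int8), [], [], name)
    values = np.vstack(rows)
    feature_ids = [f"bit{i}" for i in range(values.shape[1])]
    return FeatureTable(values, drugs, feature_ids, name)


def build_interaction_matrix(
    pairs: list[tuple[str, str]], drug_order: list[str], adr_order: list[str]
) -> InteractionMatrix:
    """Assemble the ADR × drug binary matrix from (drug, adr) pairs."""
    values = _pairs_to_matrix(pairs, drug_order, adr_order).T
    return InteractionMatrix(values, adr_order, drug_order)


def build_feature_table(
    pairs: list[tuple[str, str]],
    drug_order: list[str],
    feature_order: list[str],
    name: str = "feature",
) -> FeatureTable:
    """Assemble the drug × feature binary matrix from (drug, feature) pairs."""
    values = _pairs_to_matrix(pairs, drug_order, feature_order)
    return FeatureTable(values, drug_order, feature_order, name)


def build_matrix(
    pairs: list[tuple[str, str]],
    drug_order: list[str],
    item_order: list[str],
    role: str = "adr",
    name: str = "feature",
):
    """Dispatch to the interaction- or feature-matrix builder by role."""
    if role == "adr":
        return build_interaction_matrix(pairs, drug_order, item_order)
    if role == "feature":
        return build_feature_table(pairs, drug_order, item_order, name)
    raise ValueError(f"role must be 'adr' or 'feature', got {role!r}")


def _pairs_to_matrix(
    pairs: list[tuple[str, str]], drug_order: list[str], item_order: list[str]
) -> np.ndarray:
    drug_idx = {d: i for i, d in enumerate(drug_order)}
    item_idx = {a: i for i, a in enumerate(item_order)}
    bad = [
        (d, a) for d, a in pairs if d not in drug_idx or a not in item_idx
    ]
    if bad:
        raise KeyError(f"pairs with unknown ids: {bad[:10]}")
    values = np.zeros((len(drug_order), len(item_order)), dtype=np.int8)
    for d, a in pairs:
        values[drug_idx[d], item_idx[a]] = 1
    return values


def filter_featureless_drugs(
    Y: InteractionMatrix, features: list[FeatureTable]
) -> InteractionMatrix:
    """Drop drugs with no usable feature information in any table.

    A drug is kept iff at least one feature table has a row for it with at
    least one nonzero bit (an all-zero row carries no RBF similarity
    information beyond a constant, so it counts as featureless).
    """
    usable: set[str] = set()
    for table in features:
        nonzero = np.asarray(table.values).sum(axis=1) > 0
        usable.update(d for d, keep in zip(table.drug_ids, nonzero) if keep)
    kept = [d for d in Y.drug_ids if d in usable]
    if not kept:
        raise ValueError("no drug has features in any table")
    return Y.subset_drugs(kept)


def split_holdout(drug_ids: list[str], fraction: float, seed: int) -> SplitPlan:
    """Reserve a uniform random fraction of drugs as a hold-out ("new") set.

    The hold-out size is round-half-up of ``fraction * N``; e.g. 766 drugs at
    25% give 192 hold-out drugs.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(drug_ids) < 2:
        raise ValueError("need at least 2 drugs to split")
    n = len(drug_ids)
    n_new = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    chosen = set(rng.permutation(n)[:n_new].tolist())
    new = [d for i, d in enumerate(drug_ids) if i in chosen]
    known = [d for i, d in enumerate(drug_ids) if i not in chosen]
    return SplitPlan(known, new, seed)


def mask_new_drugs(
    Y0: InteractionMatrix, new_drug_ids: list[str]
) -> tuple[InteractionMatrix, InteractionMatrix]:
    """Split Y0 into a known-drug training matrix and the withheld truth.

    ``Y_known`` keeps only known-drug columns (no trace of the new drugs);
    ``Y_truth_new`` carries the withheld labels for scoring only.
    """
    new_set = set(new_drug_ids)
    unknown = new_set - set(Y0.drug_ids)
    if unknown:
        raise KeyError(f"new drug ids not in matrix: {sorted(unknown)}")
    known = [d for d in Y0.drug_ids if d not in new_set]
    if not known:
        raise ValueError("masking all drugs leaves no training data")
    Y_known = Y0.subset_drugs(known)
    Y_truth_new = Y0.subset_drugs(list(new_drug_ids))
    return Y_known, Y_truth_new
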