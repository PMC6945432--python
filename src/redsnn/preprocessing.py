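"""Feature encoding, imputation, standardization, and data partitioning.

Ordinal covariates map to a single numeric channel preserving order;
categorical covariates expand to one-hot channels (an "Unknown" level, when
declared, absorbs missing entries).  Continuous source columns bin to ordered
levels first: age in years at 30-year intervals, tumor size at 80 mm.
Missing inputs propagate as NaN cells through encoding; k-NN imputation and
z-scoring are fitted on training rows only so no test information leaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .synthetic import OUTCOME_COLUMNS, CohortSpec

__all__ = [
    "ColumnEncoding",
    "EncodingSchema",
    "default_encoding_schema",
    "encode_features",
    "SplitPlan",
    "split_train_test",
    "kfold",
    "knn_impute",
    "standardize",
    "Preprocessor",
]


@dataclass(frozen=True)
class ColumnEncoding:
    """How one raw covariate becomes feature channels.

    kind "ordinal": one numeric channel; ``bins`` (optional) cut a continuous
    source into ordered levels 1..len(bins)+1 before encoding.
    kind "onehot": one channel per level in ``levels``; a level literally named
    ``"Unknown"`` receives missing entries.
    """

    name: str
    kind: str  # "ordinal" | "onehot"
    levels: tuple[str, ...] | None = None
    bins: tuple[float, ...] | None = None

    @property
    def width(self) -> int:
        return 1 if self.kind == "ordinal" else len(self.levels)


@dataclass(frozen=True)
class EncodingSchema:
    columns: tuple[ColumnEncoding, ...]

    @property
    def width(self) -> int:
        return sum(c.width for c in self.columns)

    @property
    def feature_names(self) -> list[str]:
        names = []
        for col in self.columns:
            if col.kind == "ordinal":
                names.append(col.name)
            else:
                names.extend(f"{col.name}={lvl}" for lvl in col.levels)
        return names

    def validate_against(self, table: pd.DataFrame) -> None:
        covs = set(table.columns) - set(OUTCOME_COLUMNS)
        declared = {c.name for c in self.columns}
        if covs != declared:
            raise ValueError(
                f"schema/table mismatch: only in table {sorted(covs - declared)}, "
                f"only in schema {sorted(declared - covs)}"
            )


def default_encoding_schema(spec: CohortSpec | None = None) -> EncodingSchema:
    """Schema matched to a cohort spec (default: the shipped 14-covariate
    cohort, which encodes to width 26).  Categorical covariates with declared
    missingness gain an explicit Unknown level."""
    from .synthetic import default_cohort_spec

    spec = spec or default_cohort_spec()
    cols = []
    for cov in spec.covariates:
        if cov.kind == "categorical":
            levels = cov.levels + (("Unknown",) if cov.missing_rate > 0 else ())
            cols.append(ColumnEncoding(cov.name, "onehot", levels=levels))
        elif cov.kind == "ordinal":
            cols.append(ColumnEncoding(cov.name, "ordinal"))
        else:
            cols.append(ColumnEncoding(cov.name, "ordinal", bins=cov.bins))
    return EncodingSchema(tuple(cols))


def encode_features(table: pd.DataFrame, schema: EncodingSchema) -> pd.DataFrame:
    """Encode a cohort table into a numeric feature matrix (NaN = missing).

    Imputation is a separate stage: missing ordinal cells stay NaN, and
    missing categorical cells without an Unknown level leave NaN across that
    covariate's one-hot channels.
    """
    schema.validate_against(table)
    n = len(table)
    out = {}
    for col in schema.columns:
        raw = table[col.name]
        if col.kind == "ordinal":
            vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
            if col.bins is not None:
                lev = np.digitize(vals, col.bins).astype(float) + 1.0
                lev[np.isnan(vals)] = np.nan
                vals = lev
            out[col.name] = vals
        else:
            sraw = raw.astype(object)
            missing = pd.isna(sraw).to_numpy()
            seen = set(sraw[~missing].astype(str))
            unknown_level = "Unknown" in col.levels
            unseen = seen - set(col.levels)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} in covariate {col.name!r}"
                )
            for lvl in col.levels:
                chan = np.zeros(n)
                if lvl == "Unknown":
                    chan[missing] = 1.0
                chan[(~missing) & (sraw.astype(str).to_numpy() == lvl)] = 1.0
                if missing.any() and not unknown_level:
                    chan[missing] = np.nan
                out[f"{col.name}={lvl}"] = chan
    X = pd.DataFrame(out, index=table.index)
    assert X.shape[1] == schema.width
    return X


@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float = 0.2
    k: int = 5
    seed: int = 0


def split_train_test(n: int, plan: SplitPlan) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; |test| = round(n * fraction), disjoint, exhaustive."""
    if not 0.0 < plan.test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(round(n * plan.test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(plan.seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def kfold(train_indices: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold over the (absolute) training indices; validation folds
    partition the training set with sizes differing by at most one."""
    train_indices = np.asarray(train_indices)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(train_indices):
        raise ValueError("k exceeds the number of training rows")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_indices[fit], train_indices[val])
        for fit, val in splitter.split(train_indices)
    ]


def knn_impute(fit: np.ndarray, apply: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill missing cells in ``apply`` from the k nearest fit rows.

    Distances are NaN-aware Euclidean over mutually observed channels (scaled
    by the observed fraction); neighbor values average uniformly.  Observed
    cells pass through unchanged.
    """
    fit = np.asarray(fit, dtype=float)
    apply = np.asarray(apply, dtype=float)
    all_missing = np.isnan(fit).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"column(s) {np.where(all_missing)[0].tolist()} missing in every fit row"
        )
    imputer = KNNImputer(n_neighbors=min(k, fit.shape[0]))
    imputer.fit(fit)
    return imputer.transform(apply)


def standardize(fit: np.ndarray, apply: np.ndarray) -> np.ndarray:
    """Z-score ``apply`` per column using mean/SD computed on ``fit`` rows;
    constant fit columns map to 0."""
    scaler = StandardScaler().fit(np.asarray(fit, dtype=float))
    return scaler.transform(np.asarray(apply, dtype=float))


@dataclass
class Preprocessor:
    """Fitted imputation + scaling state, persistable as JSON.

    Fit statistics (neighbor set, column means/SDs) come from training rows
    only, so transforming new rows can never feed information back.
    """

    schema: EncodingSchema
    n_neighbors: int = 5
    _imputer: KNNImputer | None = field(default=None, repr=False)
    _scaler: StandardScaler | None = field(default=None, repr=False)

    def fit(self, X_fit: np.ndarray) -> "Preprocessor":
        X_fit = np.asarray(X_fit, dtype=float)
        all_missing = np.isnan(X_fit).all(axis=0)
        if all_missing.any():
            raise ValueError("column missing in every fit row; cannot impute")
        self._imputer = KNNImputer(n_neighbors=min(self.n_neighbors, X_fit.shape[0]))
        filled = self._imputer.fit_transform(X_fit)
        self._scaler = StandardScaler().fit(filled)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._imputer is None:
            raise RuntimeError("Preprocessor is not fitted")
        return self._scaler.transform(self._imputer.transform(np.asarray(X, dtype=float)))

    # --- persistence -----------------------------------------------------
    def to_json(self) -> str:
        if self._imputer is None:
            raise RuntimeError("Preprocessor is not fitted")
        payload = {
            "schema": [
                {"name": c.name, "kind": c.kind, "levels": c.levels, "bins": c.bins}
                for c in self.schema.columns
            ],
            "n_neighbors": self.n_neighbors,
            "means": self._scaler.mean_.tolist(),
            "sds": self._scaler.scale_.tolist(),
            "fit_matrix": np.where(
                np.isnan(self._imputer._fit_X), None, self._imputer._fit_X
            ).tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "Preprocessor":
        payload = json.loads(text)
        schema = EncodingSchema(
            tuple(
                ColumnEncoding(
                    c["name"],
                    c["kind"],
                    tuple(c["levels"]) if c["levels"] else None,
                    tuple(c["bins"]) if c["bins"] else None,
                )
                for c in payload["schema"]
            )
        )
        pre = cls(schema=schema, n_neighbors=payload["n_neighbors"])
        fit_matrix = np.array(
            [[np.nan if v is None else v for v in row] for row in payload["fit_matrix"]],
            dtype=float,
        )
        pre._imputer = KNNImputer(n_neighbors=min(pre.n_neighbors, fit_matrix.shape[0]))
        pre._imputer.fit(fit_matrix)
        pre._scaler = StandardScaler()
        pre._scaler.mean_ = np.array(payload["means"])
        pre._scaler.scale_ = np.array(payload["sds"])
        pre._scaler.var_ = pre._scaler.scale_ ** 2
        pre._scaler.n_features_in_ = len(payload["means"])
        return pre
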