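"""Labeled feature tables: reading, writing, imputation, splitting, simulation.

The unit of all I/O is the :class:`FeatureTable` — a numeric record × feature
matrix with an explicit missing-value mask and a nominal class column drawn
from a fixed vocabulary (which may contain classes with zero records, as the
16-class arrhythmia vocabulary does).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureTable",
    "FixtureSpec",
    "MeanImputer",
    "ARRHYTHMIA_CLASS_COUNTS",
    "read_feature_table",
    "write_csv",
    "write_arff",
    "fit_mean_imputer",
    "apply_imputer",
    "stratified_split",
    "stratified_class_counts",
    "generate_fixture",
    "simulate",
]

#: Tokens recognized as missing in CSV feature cells (ARFF uses "?").
MISSING_TOKENS = {"?", "", "NA", "N/A", "NaN", "nan"}

#: The 16-class arrhythmia vocabulary with per-class record counts
#: (452 records in total; three AV-block classes have zero records).
ARRHYTHMIA_CLASS_COUNTS: dict[str, int] = {
    "Normal": 245,
    "IC-CAD": 44,
    "OAMI": 15,
    "OIMI": 15,
    "ST": 13,
    "SB": 25,
    "VPC": 3,
    "SPC": 2,
    "LBBB": 9,
    "RBBB": 50,
    "1-DAVB": 0,
    "2-DAVB": 0,
    "3-DAVB": 0,
    "LVH": 4,
    "AF": 5,
    "Others": 22,
}


@dataclass
class FeatureTable:
    """A labeled numeric feature table with an explicit missing-value mask.

    Parameters
    ----------
    feature_names : list of str
        Unique column identifiers; length equals the matrix width.
    values : ndarray of shape (n_rows, n_features)
        Float matrix; missing entries are ``NaN`` (never silently dropped).
    class_labels : ndarray of shape (n_rows,)
        Nominal class label per row; every label must be in the vocabulary.
    class_vocabulary : list of str
        Ordered class vocabulary. May contain classes with zero rows.
    """

    feature_names: list[str]
    values: np.ndarray
    class_labels: np.ndarray
    class_vocabulary: list[str]

    def __post_init__(self) -> None:
        self.feature_names = list(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.class_vocabulary = list(self.class_vocabulary)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("matrix width does not match feature_names")
        if self.values.shape[0] != len(self.class_labels):
            raise ValueError("matrix height does not match class_labels")
        vocab = set(self.class_vocabulary)
        bad = [c for c in self.class_labels if c not in vocab]
        if bad:
            raise ValueError(f"class labels outside vocabulary: {sorted(set(bad))!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells (True = missing)."""
        return np.isnan(self.values)

    def class_counts(self) -> dict[str, int]:
        """Per-class row counts in vocabulary order (zero-count classes kept)."""
        labels = list(self.class_labels)
        return {c: labels.count(c) for c in self.class_vocabulary}

    def select_rows(self, indices) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.feature_names,
            self.values[idx],
            self.class_labels[idx],
            self.class_vocabulary,
        )

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        pos = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        cols = [pos[f] for f in names]
        return FeatureTable(
            names, self.values[:, cols], self.class_labels, self.class_vocabulary
        )

    def to_dataframe(self, class_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[class_column] = self.class_labels
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.class_vocabulary == other.class_vocabulary
            and np.array_equal(self.class_labels, other.class_labels)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".arff":
        return "arff"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_feature_table(
    path,
    format: str | None = None,
    class_column: str = "class",
    class_vocabulary: list[str] | None = None,
) -> FeatureTable:
    """Read a labeled feature table from CSV or ARFF.

    Missing feature cells ("?" in ARFF; empty/NA tokens in CSV) become NaN in
    the matrix. Rows with a missing class label are dropped with a warning —
    only feature imputation is supported. For CSV, the vocabulary defaults to
    the sorted set of observed labels unless ``class_vocabulary`` is given;
    ARFF nominal class attributes carry their own vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if class_column not in df.columns:
            raise ValueError(f"class column {class_column!r} not in {list(df.columns)}")
        labels_raw = df[class_column].to_numpy()
        feats = df.drop(columns=[class_column])
        values = np.empty(feats.shape, dtype=float)
        for j, col in enumerate(feats.columns):
            cells = feats[col].to_numpy()
            for i, cell in enumerate(cells):
                token = cell.strip()
                if token in MISSING_TOKENS:
                    values[i, j] = np.nan
                else:
                    try:
                        values[i, j] = float(token)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric cell {cell!r} in feature {col!r} "
                            f"(row {i}) is not a recognized missing token"
                        ) from None
        feature_names = list(feats.columns)
        labels = np.array([s.strip() for s in labels_raw], dtype=object)
        vocab = class_vocabulary
    elif fmt == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        names = list(meta.names())
        if class_column not in names:
            raise ValueError(f"class column {class_column!r} not in {names}")
        feature_names = [n for n in names if n != class_column]
        for n in feature_names:
            if meta[n][0] != "numeric":
                raise ValueError(f"feature {n!r} is not numeric in ARFF header")
        values = np.column_stack(
            [np.asarray(data[n], dtype=float) for n in feature_names]
        ) if len(data) else np.empty((0, len(feature_names)))
        raw = data[class_column]
        labels = np.array(
            [v.decode() if isinstance(v, bytes) else str(v) for v in raw],
            dtype=object,
        )
        vocab = class_vocabulary or list(meta[class_column][1])
    else:
        raise ValueError(f"unknown format {fmt!r}")

    keep = np.array([lab not in MISSING_TOKENS for lab in labels], dtype=bool)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} row(s) with missing class label",
            stacklevel=2,
        )
        values, labels = values[keep], labels[keep]
    if vocab is None:
        vocab = sorted(set(labels))
    return FeatureTable(feature_names, values, labels, vocab)


def write_csv(table: FeatureTable, path, class_column: str = "class") -> None:
    """Write a table as CSV; missing cells are emitted as empty strings."""
    df = table.to_dataframe(class_column)
    df.to_csv(path, index=False, na_rep="")


def write_arff(
    table: FeatureTable, path, relation: str = "table", class_column: str = "class"
) -> None:
    """Write a table as ARFF with a nominal class attribute.

    The nominal attribute lists the full vocabulary, so zero-count classes
    survive a round-trip (CSV cannot express them).
    """
    lines = [f"@relation {relation}", ""]
    for name in table.feature_names:
        lines.append(f"@attribute {name} numeric")
    vocab = ",".join(table.class_vocabulary)
    lines.append(f"@attribute {class_column} {{{vocab}}}")
    lines.append("")
    lines.append("@data")
    for row, label in zip(table.values, table.class_labels):
        cells = ["?" if np.isnan(v) else repr(float(v)) for v in row]
        cells.append(str(label))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mean imputation
# ---------------------------------------------------------------------------

class MeanImputer(TransformerMixin, BaseEstimator):
    """Per-feature mean (or mode) imputation.

    For every feature f the fit step computes μ_f, the mean of the observed
    (non-missing) entries; transform replaces each missing entry of f with
    μ_f and leaves observed entries untouched. ``strategy="mode"`` substitutes
    the most frequent observed value instead (for 0/1-coded features); mean
    is the default everywhere.
    """

    def __init__(self, strategy: str = "mean"):
        self.strategy = strategy

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.strategy not in ("mean", "mode"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        names = getattr(self, "_feature_names", None)
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            idx = np.flatnonzero(all_missing)
            labels = [names[i] if names else str(i) for i in idx]
            raise ValueError(
                f"feature(s) with no observed values cannot be imputed: {labels}"
            )
        if self.strategy == "mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.statistics_ = np.nanmean(X, axis=0)
        else:
            stats = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                col = X[:, j]
                obs = col[~np.isnan(col)]
                vals, counts = np.unique(obs, return_counts=True)
                stats[j] = vals[np.argmax(counts)]
            self.statistics_ = stats
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; imputer was fit on "
                f"{self.n_features_in_}"
            )
        out = X.copy()
        mask = np.isnan(out)
        out[mask] = np.broadcast_to(self.statistics_, out.shape)[mask]
        return out


def fit_mean_imputer(table: FeatureTable, strategy: str = "mean") -> MeanImputer:
    """Fit a per-feature mean imputer on a table (μ_f from observed entries)."""
    imp = MeanImputer(strategy=strategy)
    imp._feature_names = table.feature_names
    imp.fit(table.values)
    return imp


def apply_imputer(model: MeanImputer, table: FeatureTable) -> FeatureTable:
    """Replace every missing entry of feature f with the fitted μ_f."""
    if model.n_features_in_ != table.n_features:
        raise ValueError(
            f"imputer covers {model.n_features_in_} features; "
            f"table has {table.n_features}"
        )
    return FeatureTable(
        table.feature_names,
        model.transform(table.values),
        table.class_labels,
        table.class_vocabulary,
    )


# ---------------------------------------------------------------------------
# Stratified 70/30 split
# ---------------------------------------------------------------------------

def stratified_class_counts(
    counts: list[int], train_fraction: float
) -> list[int]:
    """Per-class train counts under largest-remainder rounding.

    The overall train size is round(train_fraction × N); each class gets the
    floor of its exact quota and the leftover seats go to the largest
    fractional remainders (ties broken by class order). Any non-empty class
    rounded to zero is bumped to one train row, so rare classes are always
    trainable.
    """
    counts = [int(c) for c in counts]
    n = sum(counts)
    total_train = int(round(train_fraction * n))
    quotas = [train_fraction * c for c in counts]
    base = [int(np.floor(q)) for q in quotas]
    seats = total_train - sum(base)
    order = sorted(range(len(counts)), key=lambda i: (-(quotas[i] - base[i]), i))
    out = list(base)
    for i in order[:max(seats, 0)]:
        out[i] += 1
    for i, c in enumerate(counts):
        out[i] = min(out[i], c)
        if c >= 1 and out[i] == 0:
            out[i] = 1  # a 1-row class goes to train
    return out


def stratified_split(
    table: FeatureTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Class-stratified train/test partition, deterministic given ``seed``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = list(table.class_counts().values())
    train_counts = stratified_class_counts(counts, train_fraction)
    labels = table.class_labels
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls, k in zip(table.class_vocabulary, train_counts):
        rows = np.flatnonzero(labels == cls)
        perm = rng.permutation(rows)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return table.select_rows(sorted(train_idx)), table.select_rows(sorted(test_idx))


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Recipe for a synthetic arrhythmia-style feature table.

    Defaults emulate the study table: 452 records, 279 numeric features, the
    16-class vocabulary with its per-class counts (three AV-block classes
    empty), 10 planted informative features whose per-class means are drawn
    N(0, Δ²) with Δ = 1.5 sd, 20 redundant feature pairs at |r| ≈ 0.95 built
    from noise features, and 2 % missing cells.
    """

    n_features: int = 279
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(ARRHYTHMIA_CLASS_COUNTS)
    )
    planted_features: list[int] | None = None
    n_planted: int = 10
    effect_size: float = 1.5
    n_redundant_pairs: int = 20
    redundant_rho: float = 0.95
    missing_rate: float = 0.02
    seed: int = 0

    def resolved_planted(self) -> list[int]:
        """Planted feature indices, evenly spread if not given explicitly."""
        if self.planted_features is not None:
            return list(self.planted_features)
        if self.n_planted == 0:
            return []
        idx = np.linspace(0, self.n_features - 1, self.n_planted)
        return sorted(set(int(round(i)) for i in idx))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_features"] = self.resolved_planted()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        d.pop("n_planted", None) if d.get("planted_features") is not None else None
        return cls(**{k: v for k, v in d.items() if k in
                      {f.name for f in dataclasses.fields(cls)}})


def generate_fixture(spec: FixtureSpec) -> FeatureTable:
    """Generate a synthetic labeled table from a :class:`FixtureSpec`.

    Noise features are i.i.d. standard normal; planted features receive
    class-dependent mean shifts; redundant partners are ρ·source +
    sqrt(1−ρ²)·noise so the population correlation equals ρ; missing cells
    are injected uniformly at ``missing_rate``. Per-class counts match the
    spec exactly and output is bitwise-reproducible for a given seed.
    """
    counts = spec.class_counts
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be non-negative")
    planted = spec.resolved_planted()
    if planted and (min(planted) < 0 or max(planted) >= spec.n_features):
        raise ValueError("planted feature index out of range")
    rng = np.random.default_rng(spec.seed)
    vocab = list(counts)
    labels = np.array(
        [c for c, k in counts.items() for _ in range(k)], dtype=object
    )
    n = len(labels)
    rng.shuffle(labels)
    X = rng.standard_normal((n, spec.n_features))

    class_index = {c: i for i, c in enumerate(vocab)}
    y_idx = np.array([class_index[c] for c in labels])
    for f in planted:
        shifts = spec.effect_size * rng.standard_normal(len(vocab))
        X[:, f] += shifts[y_idx]

    # Redundant pairs drawn from the non-planted pool, disjoint.
    pool = [j for j in range(spec.n_features) if j not in set(planted)]
    need = 2 * spec.n_redundant_pairs
    if need > len(pool):
        raise ValueError("not enough noise features for the redundant pairs")
    chosen = rng.choice(len(pool), size=need, replace=False)
    rho = spec.redundant_rho
    pairs = []
    for k in range(spec.n_redundant_pairs):
        a, b = pool[chosen[2 * k]], pool[chosen[2 * k + 1]]
        X[:, b] = rho * X[:, a] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        pairs.append((a, b))

    if spec.missing_rate > 0:
        miss = rng.uniform(size=X.shape) < spec.missing_rate
        X[miss] = np.nan

    names = [f"feat_{j:04d}" for j in range(spec.n_features)]
    table = FeatureTable(names, X, labels, vocab)
    table.planted_features = [names[j] for j in planted]  # provenance for tests
    table.redundant_pairs = [(names[a], names[b]) for a, b in pairs]
    return table


def simulate(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write a fixture as CSV + ARFF plus a JSON sidecar recording the spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = generate_fixture(spec)
    paths = {
        "csv": out_dir / "fixture.csv",
        "arff": out_dir / "fixture.arff",
        "spec": out_dir / "fixture.spec.json",
    }
    write_csv(table, paths["csv"])
    write_arff(table, paths["arff"], relation="synthetic_arrhythmia")
    sidecar = {
        "spec": spec.to_dict(),
        "planted_features": table.planted_features,
        "redundant_pairs": table.redundant_pairs,
    }
    paths["spec"].write_text(json.dumps(sidecar, indent=2) + "\n")
    return paths
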