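"""Tabular preparation pipeline.

Fixed stage order: split -> missingness filter -> outlier winsorizing ->
masked-NMF imputation -> min-max scaling -> per-feature normalizing
transform selection -> (classification only) target discretization and
SMOTE+ENN class balancing.  Preparation statistics are always fitted
within one partition and never shared with the other; the held-out
validation partition is never resampled.

Transformer classes follow the scikit-learn fit/transform contract; the
module-level functions are thin one-shot wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import FeatureAgglomeration
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler, PowerTransformer, QuantileTransformer

from .exceptions import ConfigurationError, EvaluationError

__all__ = [
    "split_data",
    "drop_high_missing",
    "winsorize",
    "nmf_impute",
    "minmax_scale",
    "select_transform",
    "agglomerate_summary",
    "discretize_target",
    "balance_classes",
    "MissingnessFilter",
    "Winsorizer",
    "NMFImputer",
    "TransformSelector",
    "SMOTEENN",
    "prepare_partition",
]


# ---------------------------------------------------------------------------
# splitting

def split_data(
    df: pd.DataFrame, fraction: float = 0.7, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row partition into (train_test, validation).

    ``fraction`` is the train/test share (~0.7 by convention).  The two
    partitions are disjoint and exhaustive; all later preparation
    statistics are fitted independently within each partition.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    n = len(df)
    n_train = round(n * fraction)
    if n_train < 2 or n - n_train < 2:
        raise ConfigurationError("partition would leave < 2 samples")
    seed = int(rng.integers(2**31)) if rng is not None else None
    train, val = train_test_split(df, train_size=n_train, random_state=seed, shuffle=True)
    return train, val


# ---------------------------------------------------------------------------
# missingness filter

class MissingnessFilter(BaseEstimator, TransformerMixin):
    """Drop features whose missing fraction strictly exceeds the cutoff
    (a feature at exactly the cutoff is kept)."""

    def __init__(self, max_missing_fraction: float = 0.4):
        self.max_missing_fraction = max_missing_fraction

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 <= self.max_missing_fraction <= 1:
            raise ConfigurationError("max_missing_fraction must be in [0, 1]")
        frac = X.isna().mean(axis=0)
        self.keep_ = list(frac.index[frac <= self.max_missing_fraction])
        self.dropped_ = list(frac.index[frac > self.max_missing_fraction])
        if not self.keep_:
            raise ConfigurationError("all features exceed the missingness cutoff")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.keep_]


def drop_high_missing(df: pd.DataFrame, max_missing_fraction: float = 0.4) -> pd.DataFrame:
    return MissingnessFilter(max_missing_fraction).fit_transform(df)


# ---------------------------------------------------------------------------
# winsorizing

class Winsorizer(BaseEstimator, TransformerMixin):
    """Clip each feature to mean +/- z standard deviations.

    Moments are computed ignoring missing entries (population standard
    deviation); zero-variance features are left unchanged.  Values are
    clipped, not deleted, so the sample size is preserved and the
    operation is idempotent.
    """

    def __init__(self, z: float = 3.0):
        self.z = z

    def fit(self, X: pd.DataFrame, y=None):
        if self.z <= 0:
            raise ConfigurationError("z must be > 0")
        mean = X.mean(axis=0, skipna=True)
        sd = X.std(axis=0, ddof=0, skipna=True)
        self.lower_ = mean - self.z * sd
        self.upper_ = mean + self.z * sd
        zero = sd == 0
        self.lower_[zero] = -np.inf
        self.upper_[zero] = np.inf
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.clip(lower=self.lower_, upper=self.upper_, axis=1)


def winsorize(df: pd.DataFrame, z: float = 3.0) -> pd.DataFrame:
    return Winsorizer(z).fit_transform(df)


# ---------------------------------------------------------------------------
# masked-NMF imputation

def _masked_nmf(
    X: np.ndarray,
    mask: np.ndarray,
    rank: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[float]]:
    """Multiplicative-update factorization fit only on observed cells.

    Minimizes ``||mask * (X - WH)||_F^2``; returns the reconstruction
    and the per-iteration observed-cell loss (non-increasing).
    """
    eps = 1e-10
    n, m = X.shape
    scale = np.sqrt(max(X[mask].mean(), eps) / rank)
    W = rng.uniform(0, 1, size=(n, rank)) * scale + eps
    H = rng.uniform(0, 1, size=(rank, m)) * scale + eps
    Xm = np.where(mask, X, 0.0)
    losses: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        R = np.where(mask, W @ H, 0.0)
        W *= (Xm @ H.T) / np.maximum(R @ H.T, eps)
        R = np.where(mask, W @ H, 0.0)
        H *= (W.T @ Xm) / np.maximum(W.T @ R, eps)
        loss = float(np.sum((np.where(mask, X - W @ H, 0.0)) ** 2))
        losses.append(loss)
        if np.isfinite(prev) and prev - loss <= tol * max(prev, eps):
            break
        prev = loss
    return W @ H, losses


class NMFImputer(BaseEstimator):
    """Impute missing cells with a low-rank non-negative factorization.

    The matrix is min-shifted to be non-negative (shift reversed after),
    the factorization is fit only on observed cells, missing cells are
    replaced by the reconstruction, and observed cells are untouched.
    Like manifold embedders, the imputation is transductive:
    ``fit_transform`` is the supported entry point.
    """

    def __init__(
        self,
        rank: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-5,
        random_state: int | None = None,
    ):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        values = X.to_numpy(dtype=float)
        mask = ~np.isnan(values)
        if not mask.all():
            empty_rows = np.where(~mask.any(axis=1))[0]
            if len(empty_rows):
                raise EvaluationError(
                    f"row {X.index[empty_rows[0]]!r} is fully missing"
                )
            empty_cols = np.where(~mask.any(axis=0))[0]
            if len(empty_cols):
                raise EvaluationError(
                    f"column {X.columns[empty_cols[0]]!r} is fully missing"
                )
        else:
            self.losses_ = []
            return X.copy()
        rank = self.rank or min(10, max(1, X.shape[1] // 4))
        if rank < 1:
            raise ConfigurationError("rank must be >= 1")
        shift = min(float(np.nanmin(values)), 0.0)
        rng = np.random.default_rng(self.random_state)
        recon, losses = _masked_nmf(
            values - shift, mask, rank, self.max_iter, self.tol, rng
        )
        self.losses_ = losses
        out = values.copy()
        out[~mask] = (recon + shift)[~mask]
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def nmf_impute(
    df: pd.DataFrame,
    rank: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    seed = int(rng.integers(2**31)) if rng is not None else None
    return NMFImputer(rank, max_iter, tol, seed).fit_transform(df)


# ---------------------------------------------------------------------------
# scaling and transform selection

def minmax_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Map each feature to [0, 1]; constant features map to 0."""
    if df.isna().any().any():
        raise EvaluationError("missing values present; impute first")
    scaled = MinMaxScaler().fit_transform(df.to_numpy(dtype=float))
    return pd.DataFrame(scaled, index=df.index, columns=df.columns)


def _normality_score(x: np.ndarray) -> float:
    """|sample skewness| + |excess kurtosis| (0 for a normal)."""
    return abs(float(stats.skew(x))) + abs(float(stats.kurtosis(x)))


def select_transform(x, random_state: int | None = None):
    """Pick the transform making one feature look most normal.

    Candidates: identity, rank-based normal-quantile transform, and a
    Yeo-Johnson power transform; the lowest ``|skew| + |excess
    kurtosis|`` score wins, ties going to identity.  Needs >= 20
    non-missing values; a constant vector is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 20:
        raise EvaluationError("need >= 20 non-missing values for the skew test")
    if np.ptp(obs) == 0:
        return x, "identity"
    col = x.reshape(-1, 1)
    candidates = {"identity": x}
    qt = QuantileTransformer(
        n_quantiles=min(len(obs), 1000),
        output_distribution="normal",
        random_state=random_state,
    )
    candidates["quantile_normal"] = qt.fit_transform(col).ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates["power"] = (
            PowerTransformer("yeo-johnson").fit_transform(col).ravel()
        )
    scores = {
        label: _normality_score(v[~np.isnan(v)]) for label, v in candidates.items()
    }
    best = min(scores, key=lambda lab: (scores[lab], lab != "identity"))
    if scores["identity"] <= scores[best]:
        best = "identity"
    return candidates[best], best


class TransformSelector(BaseEstimator, TransformerMixin):
    """Apply :func:`select_transform` column-wise, remembering choices."""

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        out = {}
        self.choices_ = {}
        for col in X.columns:
            values, label = select_transform(X[col].to_numpy(), self.random_state)
            out[col] = values
            self.choices_[col] = label
        return pd.DataFrame(out, index=X.index)


# ---------------------------------------------------------------------------
# item agglomeration

def agglomerate_summary(items: pd.DataFrame) -> pd.Series:
    """Summarize a block of questionnaire items as one continuous score.

    Items are standardized and recursively merged by Ward-linkage
    feature agglomeration down to a single cluster, whose pooled value
    (the mean of the standardized items) is returned on the
    standardized scale.  Symmetric in item order.
    """
    if items.shape[1] < 2:
        raise ConfigurationError("need >= 2 items to agglomerate")
    if items.isna().any().any():
        raise EvaluationError("missing values present; impute first")
    values = items.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / sd
    agg = FeatureAgglomeration(n_clusters=1, linkage="ward")
    summary = agg.fit_transform(z).ravel()
    return pd.Series(summary, index=items.index, name="summary")


# ---------------------------------------------------------------------------
# targets

def discretize_target(scores, cutoff: float) -> np.ndarray:
    """Binary case labels: 1 iff score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = (scores > cutoff).astype(int)
    if labels.min() == labels.max():
        raise ConfigurationError(
            f"cutoff {cutoff} puts every sample in one class"
        )
    return labels


# ---------------------------------------------------------------------------
# class balancing (SMOTE oversampling + edited-nearest-neighbour cleaning)

class SMOTEENN(BaseEstimator):
    """Synthetic minority oversampling followed by neighbourhood cleaning.

    SMOTE: new minority samples are drawn on segments between a random
    minority sample and one of its k nearest minority neighbours
    (k = 5, reduced to minority - 1 when the minority class has fewer
    than 6 members) until the classes reach parity.  ENN: every sample
    (either class) whose k = 3 nearest neighbours majority-vote against
    its label is removed.  Applied to train/test data only — held-out
    validation data must stay native.
    """

    def __init__(self, k_smote: int = 5, k_enn: int = 3):
        self.k_smote = k_smote
        self.k_enn = k_enn

    def fit_resample(self, X, y, rng: np.random.Generator):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ConfigurationError("binary target required")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min < 2:
            raise ConfigurationError("minority class needs >= 2 samples")

        X_res, y_res = X, y
        n_new = int(n_maj - n_min)
        if n_new > 0:
            X_min = X[y == minority]
            k = min(self.k_smote, n_min - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
            _, neigh = nn.kneighbors(X_min)
            base = rng.integers(0, n_min, size=n_new)
            pick = rng.integers(1, k + 1, size=n_new)  # skip self at column 0
            u = rng.uniform(0, 1, size=n_new)
            partner = neigh[base, pick]
            synth = X_min[base] + u[:, None] * (X_min[partner] - X_min[base])
            X_res = np.vstack([X, synth])
            y_res = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])

        # edited nearest neighbours over all classes
        k = min(self.k_enn, len(y_res) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_res)
        _, neigh = nn.kneighbors(X_res)
        votes = y_res[neigh[:, 1:]]
        agree = (votes == y_res[:, None]).sum(axis=1)
        keep = agree >= (k / 2.0)
        # never remove a class entirely
        for c in classes:
            if not np.any(keep & (y_res == c)):
                keep |= y_res == c
        return X_res[keep], y_res[keep]


def balance_classes(X, y, rng: np.random.Generator, k_smote: int = 5, k_enn: int = 3):
    return SMOTEENN(k_smote, k_enn).fit_resample(X, y, rng)


# ---------------------------------------------------------------------------
# partition-level orchestration

@dataclass
class PartitionReport:
    dropped_features: list[str] = field(default_factory=list)
    imputed_cells: int = 0
    transform_choices: dict[str, str] = field(default_factory=dict)
    n_before_balance: int = 0
    n_after_balance: int = 0


def prepare_partition(
    df: pd.DataFrame,
    target: str,
    task: str = "regression",
    cutoff: float | None = None,
    balance: bool = False,
    rng: np.random.Generator | None = None,
    max_missing_fraction: float = 0.4,
    z: float = 3.0,
    nmf_rank: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, PartitionReport]:
    """Run the fixed pipeline on one partition; returns (X, y, report).

    ``balance`` applies SMOTE+ENN (classification, train/test partitions
    only); classification requires a ``cutoff`` to discretize the
    continuous target unless it is already binary.
    """
    rng = rng or np.random.default_rng()
    report = PartitionReport()
    y_raw = df[target].to_numpy(dtype=float)
    X = df.drop(columns=[target])

    filt = MissingnessFilter(max_missing_fraction).fit(X)
    report.dropped_features = filt.dropped_
    X = filt.transform(X)
    X = winsorize(X, z=z)
    report.imputed_cells = int(X.isna().sum().sum())
    X = nmf_impute(X, rank=nmf_rank, rng=rng)
    X = minmax_scale(X)
    selector = TransformSelector(random_state=int(rng.integers(2**31)))
    X = selector.fit_transform(X)
    report.transform_choices = selector.choices_

    if task == "classification":
        if set(np.unique(y_raw)) <= {0.0, 1.0}:
            y = y_raw.astype(int)
        else:
            if cutoff is None:
                raise ConfigurationError("classification requires a cutoff")
            y = discretize_target(y_raw, cutoff)
        report.n_before_balance = len(y)
        if balance:
            Xv, y = balance_classes(X.to_numpy(dtype=float), y, rng)
            X = pd.DataFrame(Xv, columns=X.columns)
        report.n_after_balance = len(y)
        return X, y, report

    report.n_before_balance = report.n_after_balance = len(y_raw)
    return X, y_raw, report
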