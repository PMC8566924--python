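"""Target normalization, input scaling, outlier screening and CV splitting.

Growth-trait targets are right-skewed (SEs grow with means), so they are
Box-Cox normalized before model fitting; trait columns containing exact
zeros (e.g. treatments where no roots emerged) receive a data-driven
positive shift before the power transform. Inputs are designed factor
levels, not skewed observations, and are min–max scaled to [0, 1] instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedKFold


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Box-Cox


@dataclass(frozen=True)
class BoxCoxTransform:
    """A fitted one-parameter power transform with an optional shift.

    Forward: ``((x + shift)^λ − 1)/λ`` for λ ≠ 0, ``log(x + shift)`` for
    λ = 0. The inverse is exact on the image of the fit domain.
    """

    lambda_: float
    shift: float = 0.0
    fitted: bool = True


def boxcox_fit(values) -> BoxCoxTransform:
    """Fit λ by profile maximum likelihood.

    Zeros are accommodated by shifting the column by half its smallest
    positive value before the transform; strictly positive columns are not
    shifted.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3 or not np.isfinite(x).all():
        raise PreprocessingError("need at least 3 finite values")
    if np.any(x < 0):
        raise PreprocessingError("Box-Cox requires nonnegative values")
    if np.ptp(x) == 0:
        raise PreprocessingError("constant input: nothing to normalize")
    if x.min() > 0:
        shift = 0.0
    else:
        shift = 0.5 * x[x > 0].min()
    _, lam = stats.boxcox(x + shift)
    return BoxCoxTransform(lambda_=float(lam), shift=float(shift))


def boxcox_apply(t: BoxCoxTransform, values) -> np.ndarray:
    if not t.fitted:
        raise PreprocessingError("transform not fitted")
    x = np.asarray(values, dtype=float) + t.shift
    if np.any(x <= 0):
        raise PreprocessingError("values fall outside the transform domain")
    if t.lambda_ == 0.0:
        return np.log(x)
    return (np.power(x, t.lambda_) - 1.0) / t.lambda_


def boxcox_invert(t: BoxCoxTransform, values) -> np.ndarray:
    if not t.fitted:
        raise PreprocessingError("transform not fitted")
    z = np.asarray(values, dtype=float)
    if t.lambda_ == 0.0:
        return np.exp(z) - t.shift
    base = t.lambda_ * z + 1.0
    if np.any(base <= 0):
        raise PreprocessingError(
            f"values outside the image range for λ={t.lambda_:.4g}"
        )
    return np.power(base, 1.0 / t.lambda_) - t.shift


# ---------------------------------------------------------------------------
# Input scaling


@dataclass(frozen=True)
class MinMaxScaler1:
    """Per-column min–max scaler to [0, 1], fit on training rows only.

    Degenerate (constant) columns map to 0.
    """

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X) -> "MinMaxScaler1":
        X = np.asarray(X, dtype=float)
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=np.where(ranges == 0, 1.0, ranges))

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mins) / self.ranges

    def inverse(self, Z) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.ranges + self.mins


# ---------------------------------------------------------------------------
# Repeated k-fold


@dataclass(frozen=True)
class FoldPlan:
    """Shuffled repeated k-fold split plan, reproducible from its seed."""

    k: int
    repeats: int
    seed: int
    pairs: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, (train, test) in enumerate(self.pairs):
            repeat, fold = divmod(pid, self.k)
            for idx in train:
                rows.append((pid, repeat, fold, int(idx), "train"))
            for idx in test:
                rows.append((pid, repeat, fold, int(idx), "test"))
        return pd.DataFrame(
            rows, columns=["pair_id", "repeat", "fold", "index", "role"]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_folds(n: int, k: int = 5, repeats: int = 10, seed: int = 0) -> FoldPlan:
    """Build a repeated k-fold plan over ``range(n)``.

    Within each repeat the test folds partition the index range; fold sizes
    differ by at most one.
    """
    if not 2 <= k <= n:
        raise PreprocessingError(f"need 2 <= k <= n, got k={k}, n={n}")
    rkf = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    pairs = tuple(
        (train.copy(), test.copy())
        for train, test in rkf.split(np.empty((n, 1)))
    )
    return FoldPlan(k=k, repeats=repeats, seed=seed, pairs=pairs)


# ---------------------------------------------------------------------------
# PCA outlier screen


def pca_outlier_flags(
    X, n_sd: float = 3.0, var_target: float = 0.95
) -> np.ndarray:
    """Flag rows whose PC-space score distance is extreme.

    Columns are standardized, scores are taken on the leading components
    covering at least ``var_target`` of the variance, each score is divided
    by its component's standard deviation, and a row is flagged when its
    Euclidean score distance exceeds the mean distance by more than ``n_sd``
    standard deviations.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise PreprocessingError(f"need more rows ({n}) than columns ({p})")
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=p)
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, var_target) + 1)
    comp_sd = np.sqrt(pca.explained_variance_[:m])
    comp_sd = np.where(comp_sd == 0, 1.0, comp_sd)
    dist = np.sqrt(np.sum((scores[:, :m] / comp_sd) ** 2, axis=1))
    thresh = dist.mean() + n_sd * dist.std(ddof=1)
    return dist > thresh
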