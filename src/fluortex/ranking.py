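"""Fisher linear-discriminant feature ranking.

Each texture feature is scored by the Mahalanobis-style separation

    delta2 = (mu1 - mu2)^2 / C

between the standard and anomalous classes, where ``C`` is the pooled
within-class covariance weighted by class size,

    C = (n1*C1 + n2*C2) / (n1 + n2),

with population (1/n) class covariances.  Features are ranked by
``delta2`` in descending order — a large value means small class
overlap — and classification uses the top-``k`` subset (default 8, the
configuration at which adding further features starts hurting).  The
score is invariant under affine rescaling of a feature, so differently
scaled features are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glcm import FEATURE_COLUMNS

__all__ = [
    "LdaModel",
    "FeatureRanking",
    "pooled_covariance",
    "fisher_separation",
    "lda_fit",
    "rank_features",
    "rank_scores",
    "select_top",
]

DEFAULT_TOP_K = 8


@dataclass
class LdaModel:
    """Two-class linear discriminant summary of a feature matrix.

    ``beta = C^-1 (mu1 - mu2)`` is the discriminant direction and
    ``delta2 = beta^T (mu1 - mu2)`` the squared Mahalanobis separation
    between the class means under the pooled covariance ``C``.
    """

    mu1: np.ndarray
    mu2: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    n1: int
    n2: int
    C: np.ndarray
    beta: np.ndarray
    delta2: float

    def score(self, x: np.ndarray) -> float:
        """Discriminant projection z = beta^T x."""
        return float(np.asarray(x) @ self.beta)


@dataclass
class FeatureRanking:
    """Features ordered by descending separation score."""

    ranking: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ranking]

    @property
    def scores(self) -> list[float]:
        return [score for _, score in self.ranking]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "feature": self.names,
                "score": self.scores,
            }
        )


def pooled_covariance(C1, C2, n1: int, n2: int):
    """Size-weighted pooled covariance ``(n1*C1 + n2*C2) / (n1 + n2)``."""
    C1 = np.asarray(C1, dtype=np.float64)
    C2 = np.asarray(C2, dtype=np.float64)
    if C1.shape != C2.shape:
        raise ValueError(f"covariance shapes differ: {C1.shape} vs {C2.shape}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("class sizes must be positive")
    pooled = (n1 * C1 + n2 * C2) / (n1 + n2)
    return pooled if pooled.ndim else float(pooled)


def fisher_separation(x1, x2) -> float:
    """Univariate separation ``(mu1 - mu2)^2 / C_pooled``.

    Returns 0 for identical means, and +inf (with a warning) when the
    pooled variance is zero but the means differ — a degenerate feature
    that separates the classes perfectly.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each class needs at least 2 samples")
    diff = x1.mean() - x2.mean()
    pooled = pooled_covariance(x1.var(), x2.var(), x1.size, x2.size)
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn(
            "zero pooled variance with unequal means: infinite separation",
            stacklevel=2,
        )
        return float("inf")
    return float(diff * diff / pooled)


def lda_fit(X1: np.ndarray, X2: np.ndarray) -> LdaModel:
    """Multivariate discriminant over two class sample matrices (rows = samples)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    C1 = np.cov(X1, rowvar=False, bias=True)
    C2 = np.cov(X2, rowvar=False, bias=True)
    C = np.atleast_2d(pooled_covariance(C1, C2, X1.shape[0], X2.shape[0]))
    beta = np.linalg.solve(C, mu1 - mu2)
    delta2 = float(beta @ (mu1 - mu2))
    return LdaModel(mu1, mu2, np.atleast_2d(C1), np.atleast_2d(C2),
                    X1.shape[0], X2.shape[0], C, beta, delta2)


def rank_scores(scored: list[tuple[str, float]]) -> FeatureRanking:
    """Sort precomputed (feature, score) pairs descending, stable on ties."""
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    return FeatureRanking([scored[i] for i in order])


def rank_features(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> FeatureRanking:
    """Score every feature column by class separation and sort descending.

    Ties are broken by input column order, so equal-scoring features
    keep their canonical f1..f10 ordering.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in table.columns]
        feature_cols += [
            c for c in table.columns
            if c not in feature_cols
            and c not in ("image_id", "group_id", "window_row", "window_col", "label")
        ]
    classes = set(table["label"].unique())
    if classes != {0, 1}:
        raise ValueError(f"need both classes present, got labels {sorted(classes)}")
    x_std = table[table["label"] == 0]
    x_anom = table[table["label"] == 1]
    scored = [
        (name, fisher_separation(x_anom[name].to_numpy(), x_std[name].to_numpy()))
        for name in feature_cols
    ]
    return rank_scores(scored)


def select_top(ranking: FeatureRanking, k: int = DEFAULT_TOP_K) -> list[str]:
    """First *k* ranked feature names."""
    if not (1 <= k <= len(ranking.ranking)):
        raise ValueError(f"k must be in [1, {len(ranking.ranking)}], got {k}")
    return ranking.names[:k]
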