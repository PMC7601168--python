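"""KNN super-pixel classification and grouped cross-validation.

Classification is k-nearest-neighbor on z-score-standardized features
(Euclidean distance); standardization parameters come from the training
fold only.  Majority ties break toward the anomalous class — the
clinically conservative direction, since a missed lesion costs more
than a spurious biopsy recommendation.

The evaluation protocol mirrors a grouped five-fold design: images are
partitioned into groups, and within each group every image is held out
once while the classifier trains on the group's remaining images, so a
test image's super-pixels never appear in its own training fold.
Per-fold confusion counts yield sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total, aggregated as mean +/- standard
deviation across folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "KnnModel",
    "ConfusionCounts",
    "MetricSet",
    "FoldReport",
    "knn_fit",
    "knn_predict",
    "metrics",
    "grouped_cv",
]


@dataclass
class KnnModel:
    """Stored training set for nearest-neighbor prediction."""

    X: np.ndarray  # standardized training vectors
    y: np.ndarray  # labels in {0, 1}
    k: int
    features: list[str]
    means: np.ndarray
    scales: np.ndarray
    metric: str = "euclidean"


@dataclass
class ConfusionCounts:
    """Super-pixel confusion counts (positive class = anomalous)."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass
class MetricSet:
    """Sensitivity/specificity/accuracy; NaN where the denominator is 0."""

    sensitivity: float
    specificity: float
    accuracy: float

    def defined(self, name: str) -> bool:
        return not np.isnan(getattr(self, name))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sensitivity, self.specificity, self.accuracy)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the three screening metrics from confusion counts.

    A zero denominator (e.g. no anomalous super-pixels in the fold)
    makes the corresponding metric undefined; it is reported as NaN and
    excluded from aggregates.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return MetricSet(
        sensitivity=ratio(c.TP, c.TP + c.FN),
        specificity=ratio(c.TN, c.TN + c.FP),
        accuracy=ratio(c.TP + c.TN, c.total),
    )


def knn_fit(
    table: pd.DataFrame, features: list[str], k: int = 1
) -> KnnModel:
    """Store standardized training vectors for the selected features.

    Features with zero variance in the training data are dropped with a
    warning (their z-score is undefined).
    """
    if table.empty:
        raise ValueError("empty training table")
    classes = set(table["label"].unique())
    if classes != {0, 1}:
        raise ValueError(f"training data must contain both classes, got {sorted(classes)}")
    if not (1 <= k <= len(table)):
        raise ValueError(f"k must be in [1, {len(table)}], got {k}")
    X = table[list(features)].to_numpy(dtype=np.float64)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    keep = scales > 0
    if not keep.all():
        dropped = [f for f, ok in zip(features, keep) if not ok]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        if not keep.any():
            raise ValueError("all selected features have zero training variance")
    feats = [f for f, ok in zip(features, keep) if ok]
    Xs = (X[:, keep] - means[keep]) / scales[keep]
    return KnnModel(
        X=Xs,
        y=table["label"].to_numpy(dtype=np.int8),
        k=k,
        features=feats,
        means=means[keep],
        scales=scales[keep],
    )


def knn_predict(model: KnnModel, query: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Majority label among the k nearest training points per query row.

    Accepts a single feature vector, a matrix, or a feature table;
    returns labels in {0, 1} (scalar for a single vector).  Ties break
    toward the anomalous class (1).
    """
    if isinstance(query, pd.DataFrame):
        q = query[model.features].to_numpy(dtype=np.float64)
    else:
        q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    if q.shape[1] != len(model.features):
        raise ValueError(
            f"query has {q.shape[1]} features, model expects {len(model.features)}"
        )
    qs = (q - model.means) / model.scales
    d = cdist(qs, model.X, metric=model.metric)
    nearest = np.argpartition(d, model.k - 1, axis=1)[:, : model.k]
    votes = model.y[nearest].sum(axis=1)
    pred = (2 * votes >= model.k).astype(np.int8)  # tie -> anomalous
    if not isinstance(query, pd.DataFrame) and np.asarray(query).ndim == 1:
        return pred[0]
    return pred


@dataclass
class FoldReport:
    """Cross-validation outcome: per-fold metrics plus aggregates."""

    folds: pd.DataFrame  # image_id, group_id, TP, FP, TN, FN, metrics
    predictions: pd.DataFrame  # per-super-pixel truth/prediction rows
    features: list[str]
    k: int
    aggregate: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.aggregate = {}
        for name in ("sensitivity", "specificity", "accuracy"):
            vals = self.folds[name].to_numpy(dtype=np.float64)
            vals = vals[~np.isnan(vals)]
            self.aggregate[name] = (
                (float(vals.mean()), float(vals.std())) if vals.size else
                (float("nan"), float("nan"))
            )

    def pooled_counts(self) -> ConfusionCounts:
        s = self.folds[["TP", "FP", "TN", "FN"]].sum()
        return ConfusionCounts(int(s.TP), int(s.FP), int(s.TN), int(s.FN))

    def summary(self) -> str:
        lines = [
            f"Grouped cross-validation: {len(self.folds)} folds, "
            f"k={self.k}, {len(self.features)} features",
            f"features: {', '.join(self.features)}",
            "",
            self.folds.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
        ]
        for name, (mean, sd) in self.aggregate.items():
            lines.append(f"{name:>12s}: {100 * mean:5.1f} +/- {100 * sd:.1f} %")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "features": self.features,
                "folds": self.folds.to_dict(orient="records"),
                "aggregate": {
                    name: {"mean": mean, "sd": sd}
                    for name, (mean, sd) in self.aggregate.items()
                },
            },
            indent=2,
        )


def grouped_cv(
    table: pd.DataFrame,
    features: list[str],
    k: int = 1,
    groups: dict | None = None,
    within_group: bool = True,
) -> FoldReport:
    """Leave-one-image-out evaluation within image groups.

    Parameters
    ----------
    table : DataFrame
        Concatenated feature tables with ``image_id``, ``group_id`` and
        ``label`` columns.
    features : list of str
        Feature columns used for classification.
    k : int
        Neighbor count.
    groups : mapping, optional
        Overrides the table's ``group_id`` column (image_id -> group).
    within_group : bool
        If True (default) each fold trains only on the test image's own
        group; if False, on all other images regardless of group.
    """
    table = table.copy()
    if groups is not None:
        table["group_id"] = table["image_id"].map(groups)
    sizes = table.groupby("group_id")["image_id"].nunique()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 images: {bad}")

    fold_rows = []
    pred_rows = []
    for group_id, gtab in table.groupby("group_id", sort=True):
        for image_id in sorted(gtab["image_id"].unique()):
            test = gtab[gtab["image_id"] == image_id]
            if within_group:
                train = gtab[gtab["image_id"] != image_id]
            else:
                train = table[table["image_id"] != image_id]
            model = knn_fit(train, features, k=k)
            pred = np.asarray(knn_predict(model, test))
            truth = test["label"].to_numpy(dtype=np.int8)
            c = ConfusionCounts(
                TP=int(((pred == 1) & (truth == 1)).sum()),
                FP=int(((pred == 1) & (truth == 0)).sum()),
                TN=int(((pred == 0) & (truth == 0)).sum()),
                FN=int(((pred == 0) & (truth == 1)).sum()),
            )
            m = metrics(c)
            fold_rows.append(
                {
                    "image_id": image_id, "group_id": group_id,
                    "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
            )
            pred_df = test[["image_id", "window_row", "window_col", "label"]].copy()
            pred_df = pred_df.rename(columns={"label": "truth"})
            pred_df["prediction"] = pred
            pred_rows.append(pred_df)
    return FoldReport(
        folds=pd.DataFrame(fold_rows),
        predictions=pd.concat(pred_rows, ignore_index=True),
        features=list(features),
        k=k,
    )
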