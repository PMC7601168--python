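"""End-to-end orchestration of the screening pipeline.

Per image: grayscale -> Deriche-Canny edges -> circular Hough transform
-> device removal (or pass-through) -> quadtree super-pixels -> labels
from ground truth -> GLCM features.  Over a dataset: feature ranking by
class separation, then grouped cross-validated KNN over the ranked
feature prefixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import FoldReport, grouped_cv
from .config import PipelineConfig
from .device import CircleHit, circle_crop, hough_circles, remove_device
from .edges import canny_edges, deriche_gradient
from .glcm import FEATURE_COLUMNS, EXTRA_FEATURE_COLUMNS, extract_features
from .imaging import GrayImage, LabelMask, load_image, load_mask
from .quadtree import SuperPixelGrid, label_superpixels, quadtree_divide
from .ranking import FeatureRanking, rank_features, select_top

logger = logging.getLogger("fluortex")

__all__ = ["PreprocessResult", "TrainReport", "preprocess_image",
           "extract_manifest_features", "run_training"]


@dataclass
class PreprocessResult:
    """Outcome of the per-image preprocessing chain."""

    image: GrayImage  # possibly cropped to the aperture
    mask: LabelMask | None
    grid: SuperPixelGrid
    circle: CircleHit | None  # accepted aperture, if any
    device_removed: bool


def preprocess_image(
    image: GrayImage,
    mask: LabelMask | None = None,
    config: PipelineConfig | None = None,
) -> PreprocessResult:
    """Run edge detection, device removal, quadtree division and labeling."""
    cfg = config or PipelineConfig()
    gx, gy = deriche_gradient(image, cfg.edge_alpha)
    edges = canny_edges(
        gx, gy, alpha=cfg.edge_alpha,
        low_quantile=cfg.edge_low_quantile, high_quantile=cfg.edge_high_quantile,
    )
    side = min(image.shape)
    r_min = max(int(cfg.cht_r_min_frac * side), 1)
    r_max = min(int(cfg.cht_r_max_frac * side), side // 2 + cfg.cht_r_step)
    hits = hough_circles(edges, r_min, r_max, cfg.cht_r_step)

    device_removed = bool(hits and hits[0].score >= cfg.cht_score_floor)
    if device_removed:
        circle = hits[0]
        logger.info(
            "device aperture at (%d, %d) r=%d score=%.2f: cropping",
            circle.center_row, circle.center_col, circle.radius, circle.score,
        )
        out_image = remove_device(image, hits, cfg.cht_score_floor)
        if mask is not None:
            cropped, inside = circle_crop(mask.labels, circle, fill=0)
            mask = LabelMask(cropped)
    else:
        circle = None
        out_image = image
        logger.info("no device aperture detected: pass-through")

    grid = quadtree_divide(out_image, cfg.leaf_size)
    if mask is not None:
        grid = label_superpixels(grid, mask)
    return PreprocessResult(out_image, mask, grid, circle, device_removed)


def extract_manifest_features(
    manifest: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Preprocess every manifest image and concatenate feature tables.

    Images whose mask file is missing are skipped with a warning.
    """
    cfg = config or PipelineConfig()
    tables = []
    for rec in manifest.itertuples():
        try:
            image = load_image(rec.image_path)
            mask = load_mask(rec.mask_path, image)
        except IOError as exc:
            logger.warning("skipping %s: %s", rec.image_id, exc)
            continue
        res = preprocess_image(image, mask, cfg)
        table = extract_features(
            res.image, res.grid,
            image_id=rec.image_id, group_id=rec.group_id,
            offset=cfg.glcm_offset, symmetric=cfg.glcm_symmetric,
            extra=cfg.glcm_extra_features,
        )
        tables.append(table)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


@dataclass
class TrainReport:
    """Feature ranking plus cross-validation over ranked feature prefixes."""

    ranking: FeatureRanking
    reports: dict[int, FoldReport]  # parameter count -> CV report
    best_k_features: int

    def sweep_table(self) -> pd.DataFrame:
        rows = []
        for n_feat, rep in sorted(self.reports.items()):
            row = {"n_features": n_feat}
            for name, (mean, sd) in rep.aggregate.items():
                row[name] = mean
                row[f"{name}_sd"] = sd
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Feature ranking (class-separation score):"]
        for rank, (name, score) in enumerate(self.ranking.ranking, 1):
            lines.append(f"  {rank:2d}. {name:<22s} {score:.3f}")
        lines.append("")
        lines.append("Cross-validation sweep over ranked feature prefixes:")
        lines.append(
            self.sweep_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )
        return "\n".join(lines)


def run_training(
    features: pd.DataFrame,
    config: PipelineConfig | None = None,
    sweep: bool = True,
) -> TrainReport:
    """Rank features and evaluate KNN over ranked feature subsets.

    With ``sweep=True`` the grouped CV runs for every prefix length of
    the ranking (1..n features); otherwise only for ``config.top_k``.
    """
    cfg = config or PipelineConfig()
    cols = [c for c in FEATURE_COLUMNS + EXTRA_FEATURE_COLUMNS if c in features.columns]
    ranking = rank_features(features, cols)
    n = len(ranking.ranking)
    ks = range(1, n + 1) if sweep else [min(cfg.top_k, n)]
    reports = {
        n_feat: grouped_cv(
            features, select_top(ranking, n_feat),
            k=cfg.knn_k, within_group=cfg.within_group,
        )
        for n_feat in ks
    }
    return TrainReport(ranking, reports, best_k_features=min(cfg.top_k, n))
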