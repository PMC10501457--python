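"""Mapping important patches onto named atlas regions.

Each feature is tied to one patch; overlaying the patch box on an integer
label atlas gives a histogram of region labels over the in-mask voxels,
and the modal label (smallest label id on ties) names the patch.  The
final report expands the top-k ranked features into (feature, metric,
patch, region) rows plus a deduplicated region list in first-appearance
order, which is the clinically readable summary of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtlasLabelVolume, PatchGrid, parse_feature_name
from .explainability import ImportanceRanking

UNLABELED = "(unlabeled)"


@dataclass
class PatchRegion:
    """Atlas composition of one patch."""

    patch_id: int
    primary_region: str
    fraction: float
    histogram: dict[str, float]
    unlabeled: bool = False


def map_patches_to_regions(
    grid: PatchGrid,
    atlas: AtlasLabelVolume,
    mask: np.ndarray,
) -> dict[int, PatchRegion]:
    """Histogram atlas labels over the in-mask voxels of every patch.

    Fractions are over labeled brain voxels in the box; a patch whose box
    contains no labeled brain voxel is flagged unlabeled.
    """
    mask = np.asarray(mask).astype(bool)
    if atlas.labels.shape != tuple(grid.template_shape):
        raise ValueError(
            f"atlas shape {atlas.labels.shape} != template {grid.template_shape}"
        )
    if mask.shape != tuple(grid.template_shape):
        raise ValueError("mask shape does not match the template")
    out: dict[int, PatchRegion] = {}
    for p in grid.patches:
        labs = atlas.labels[p.slices][mask[p.slices]]
        labs = labs[labs != atlas.background_label]
        if labs.size == 0:
            out[p.patch_id] = PatchRegion(
                patch_id=p.patch_id,
                primary_region=UNLABELED,
                fraction=0.0,
                histogram={},
                unlabeled=True,
            )
            continue
        values, counts = np.unique(labs, return_counts=True)
        frac = counts / counts.sum()
        # modal label; ties resolved toward the smallest label id
        best = values[np.lexsort((values, -counts))][0]
        hist = {
            atlas.name_table[int(v)]: float(f) for v, f in zip(values, frac)
        }
        out[p.patch_id] = PatchRegion(
            patch_id=p.patch_id,
            primary_region=atlas.name_table[int(best)],
            fraction=float(frac[values == best][0]),
            histogram=hist,
        )
    return out


def region_report(
    ranking: ImportanceRanking,
    region_map: dict[int, PatchRegion],
    top_k: int = 30,
) -> tuple[pd.DataFrame, list[str]]:
    """Expand the top-k features into an anatomical table.

    Returns the per-feature table (feature, metric, patch_id, region,
    fraction, score) and the deduplicated region list in first-appearance
    order.  The same region may appear for several features (several
    metrics of one patch, or neighbouring patches) but once in the list.
    """
    if not ranking.ranked_features:
        raise ValueError("empty ranking")
    rows = []
    regions: list[str] = []
    for feat in ranking.top(top_k):
        metric, pid = parse_feature_name(feat)
        pr = region_map.get(pid)
        region = pr.primary_region if pr is not None else UNLABELED
        fraction = pr.fraction if pr is not None else 0.0
        rows.append(
            {
                "feature": feat,
                "metric": metric,
                "patch_id": pid,
                "region": region,
                "fraction": fraction,
                "score": ranking.scores[feat],
            }
        )
        if region not in regions and region != UNLABELED:
            regions.append(region)
    return pd.DataFrame(rows), regions


def region_map_to_frame(region_map: dict[int, PatchRegion]) -> pd.DataFrame:
    rows = []
    for pid in sorted(region_map):
        pr = region_map[pid]
        rows.append(
            {
                "patch_id": pid,
                "primary_region": pr.primary_region,
                "fraction": pr.fraction,
                "unlabeled": pr.unlabeled,
            }
        )
    return pd.DataFrame(rows)
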