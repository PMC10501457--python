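"""Core data containers shared across the pipeline.

The pipeline moves through a small set of in-memory objects: template-space
volumes (:class:`VolumeImage`), the shared patch tiling (:class:`PatchGrid`),
per-subject correlation networks (:class:`SubjectNetwork`), the cohort
feature table (:class:`FeatureMatrix`) and an integer label atlas
(:class:`AtlasLabelVolume`).  All of them validate their structural
invariants at construction so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CLASS_LABELS = ("AD", "MCI", "NC")

LEFT = "left"
RIGHT = "right"

METRICS = ("strength", "betweenness", "eigenvector")


@dataclass
class VolumeImage:
    """A skull-stripped, template-registered intensity volume.

    Intensities outside ``brain_mask`` must be exactly zero (the
    skull-stripped contract): patch vectors are extracted from the raw box
    including non-brain voxels, which therefore contribute zeros identically
    for every subject.
    """

    intensities: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if self.intensities.shape != self.brain_mask.shape:
            raise ValueError(
                f"shape mismatch: intensities {self.intensities.shape} "
                f"vs brain_mask {self.brain_mask.shape}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        outside = self.intensities[~self.brain_mask]
        if outside.size and np.any(outside != 0):
            raise ValueError("intensities outside brain_mask must be exactly 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class Patch:
    """One axis-aligned box of the template tiling, half-open in voxels."""

    patch_id: int
    hemisphere: str
    min_corner: tuple[int, int, int]
    extent: tuple[int, int, int]
    brain_overlap_fraction: float

    def __post_init__(self) -> None:
        if self.hemisphere not in (LEFT, RIGHT):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if not 0.0 <= self.brain_overlap_fraction <= 1.0:
            raise ValueError("brain_overlap_fraction must be in [0, 1]")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(c, c + e) for c, e in zip(self.min_corner, self.extent)
        )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.extent))


@dataclass
class PatchGrid:
    """The fixed tiling shared by every subject of a cohort.

    Patch order is deterministic: left hemisphere first, then right; within
    a hemisphere, raster (C) order of the minimal corner.  Patch ids are
    sequential over the retained patches in that order.
    """

    patch_dims_mm: tuple[float, float, float]
    patches: list[Patch]
    template_shape: tuple[int, int, int]
    overlap_threshold: float = 0.10

    def __post_init__(self) -> None:
        ids = [p.patch_id for p in self.patches]
        if ids != list(range(len(ids))):
            raise ValueError("patch ids must be sequential from 0 in order")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_ids(self) -> list[int]:
        return [p.patch_id for p in self.patches]


@dataclass
class SubjectNetwork:
    """Undirected weighted network over patches for one subject.

    The adjacency is symmetric with zero diagonal; every surviving weight is
    an absolute Pearson correlation at or above ``threshold``.
    """

    subject_id: str
    adjacency: np.ndarray
    node_ids: Sequence[int]
    threshold: float = 0.3

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.node_ids):
            raise ValueError("node_ids length must match adjacency size")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be exactly 0")
        nz = a[a != 0]
        if nz.size and (np.any(nz < self.threshold - 1e-12) or np.any(nz > 1 + 1e-12)):
            raise ValueError(
                "nonzero weights must lie in [threshold, 1]"
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class FeatureMatrix:
    """Cohort feature table: one row per subject, 3 centralities per patch.

    Column order is all strengths in patch order, then all betweenness, then
    all eigenvector centralities; names are ``metric_patchID`` with
    zero-padded ids.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        m, n = self.values.shape
        if len(self.feature_names) != n:
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != n:
            raise ValueError("feature_names must be unique")
        if len(self.labels) != m or len(self.subject_ids) != m:
            raise ValueError("labels/subject_ids length must match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list[str]:
        return sorted(set(self.labels))


def feature_name(metric: str, patch_id: int) -> str:
    """Stable feature name, e.g. ``strength_0007``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return f"{metric}_{patch_id:04d}"


def parse_feature_name(name: str) -> tuple[str, int]:
    """Inverse of :func:`feature_name`."""
    metric, _, pid = name.rpartition("_")
    if metric not in METRICS:
        raise ValueError(f"cannot parse feature name {name!r}")
    return metric, int(pid)


@dataclass
class AtlasLabelVolume:
    """Integer label volume in template space plus a label-name table."""

    labels: np.ndarray
    name_table: Mapping[int, str] = field(default_factory=dict)
    background_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist()) - {self.background_label}
        missing = present - set(self.name_table)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
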