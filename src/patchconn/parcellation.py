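"""Hemisphere split and fixed-size rectangular patch tiling.

The template brain is divided at the mid-sagittal plane and each hemisphere
is covered by a regular grid of fixed-size boxes ("patches") anchored at the
minimal corner of the hemisphere's mask bounding box.  Boxes that would
extend past the hemisphere's side of the grid are dropped; of the rest, a
box is retained iff at least ``overlap_threshold`` (default 10%) of its
voxels are brain.  Patch ids are assigned left hemisphere first, then right,
in raster order of the minimal corner, and are shared by all subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LEFT, RIGHT, Patch, PatchGrid, VolumeImage


def mid_sagittal_split(n_x: int) -> tuple[int, int]:
    """Exclusive end of the left x-range and start of the right x-range.

    For odd ``n_x`` the central slice is the fissure plane and belongs to
    neither hemisphere; for even ``n_x`` the plane falls between voxels.
    """
    if n_x % 2 == 1:
        return n_x // 2, n_x // 2 + 1
    return n_x // 2, n_x // 2


def split_hemispheres(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition a brain mask into left and right hemisphere masks.

    Voxels on the mid-sagittal plane (odd x-dimension only) are assigned to
    neither hemisphere.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("no brain voxels")
    left_end, right_start = mid_sagittal_split(mask.shape[0])
    left = np.zeros_like(mask)
    right = np.zeros_like(mask)
    left[:left_end] = mask[:left_end]
    right[right_start:] = mask[right_start:]
    return left, right


def _dims_to_extent(
    dims_mm: tuple[float, float, float],
    voxel_size_mm: tuple[float, float, float],
) -> tuple[int, int, int]:
    extent = []
    for d, v in zip(dims_mm, voxel_size_mm):
        e = d / v
        if abs(e - round(e)) > 1e-9 or round(e) < 1:
            raise ValueError(
                f"patch dimension {d} mm is not an integral number of "
                f"{v} mm voxels"
            )
        extent.append(int(round(e)))
    return tuple(extent)


def _hemisphere_boxes(
    hemi_mask: np.ndarray,
    extent: tuple[int, int, int],
    x_range: tuple[int, int],
) -> list[tuple[tuple[int, int, int], float]]:
    """Candidate boxes for one hemisphere with brain-overlap fractions.

    Boxes tile from the hemisphere mask's bounding-box minimal corner and
    are dropped when they extend past the hemisphere's x-range or the grid's
    y/z bounds (no padding, no midline crossing).
    """
    if not hemi_mask.any():
        return []
    shape = hemi_mask.shape
    idx = np.nonzero(hemi_mask)
    origin = tuple(int(a.min()) for a in idx)
    limits = (x_range[1], shape[1], shape[2])
    n_box_voxels = int(np.prod(extent))
    boxes = []
    starts = [
        range(o, lim - e + 1, e) for o, lim, e in zip(origin, limits, extent)
    ]
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                sl = tuple(
                    slice(c, c + e) for c, e in zip((x0, y0, z0), extent)
                )
                frac = float(hemi_mask[sl].sum()) / n_box_voxels
                boxes.append(((x0, y0, z0), frac))
    return boxes


def tile_patches(
    mask: np.ndarray,
    dims_mm: tuple[float, float, float],
    overlap_threshold: float = 0.10,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PatchGrid:
    """Tile both hemispheres with fixed-size boxes and apply the overlap rule.

    A candidate box is retained iff the fraction of its voxels that are
    brain is ``>= overlap_threshold`` (boxes overlapping the brain by less
    than 10% are discarded by default; the exact-10% boundary is kept).
    """
    mask = np.asarray(mask).astype(bool)
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in [0, 1]")
    extent = _dims_to_extent(dims_mm, voxel_size_mm)
    if any(e > s for e, s in zip(extent, mask.shape)):
        raise ValueError(
            f"patch extent {extent} exceeds grid shape {mask.shape}"
        )
    if not mask.any():
        return PatchGrid(
            patch_dims_mm=tuple(float(d) for d in dims_mm),
            patches=[],
            template_shape=tuple(mask.shape),
            overlap_threshold=overlap_threshold,
        )
    left, right = split_hemispheres(mask)
    left_end, right_start = mid_sagittal_split(mask.shape[0])

    patches: list[Patch] = []
    for hemi_name, hemi_mask, x_range in (
        (LEFT, left, (0, left_end)),
        (RIGHT, right, (right_start, mask.shape[0])),
    ):
        boxes = _hemisphere_boxes(hemi_mask, extent, x_range)
        for corner, frac in sorted(boxes):
            if frac >= overlap_threshold:
                patches.append(
                    Patch(
                        patch_id=len(patches),
                        hemisphere=hemi_name,
                        min_corner=corner,
                        extent=extent,
                        brain_overlap_fraction=frac,
                    )
                )
    return PatchGrid(
        patch_dims_mm=tuple(float(d) for d in dims_mm),
        patches=patches,
        template_shape=tuple(mask.shape),
        overlap_threshold=overlap_threshold,
    )


def extract_patch_vector(volume: VolumeImage, patch: Patch) -> np.ndarray:
    """Voxels of one patch box in fixed raster (C) order.

    Non-brain voxels inside the box are included; by the skull-stripped
    contract they are exactly zero, identically for every subject.
    """
    for c, e, s in zip(patch.min_corner, patch.extent, volume.shape):
        if c < 0 or c + e > s:
            raise ValueError(
                f"patch {patch.patch_id} box exceeds volume shape {volume.shape}"
            )
    return volume.intensities[patch.slices].ravel(order="C").astype(float)


def extract_patch_matrix(volume: VolumeImage, grid: PatchGrid) -> np.ndarray:
    """All patch vectors of one subject, shape (n_patches, patch_voxels)."""
    if volume.shape != grid.template_shape:
        raise ValueError(
            f"volume shape {volume.shape} != template {grid.template_shape}"
        )
    return np.stack([extract_patch_vector(volume, p) for p in grid.patches])


def grid_to_frame(grid: PatchGrid) -> pd.DataFrame:
    """Tabular form of a PatchGrid (one row per patch)."""
    return pd.DataFrame(
        {
            "patch_id": [p.patch_id for p in grid.patches],
            "hemisphere": [p.hemisphere for p in grid.patches],
            "min_x": [p.min_corner[0] for p in grid.patches],
            "min_y": [p.min_corner[1] for p in grid.patches],
            "min_z": [p.min_corner[2] for p in grid.patches],
            "extent_x": [p.extent[0] for p in grid.patches],
            "extent_y": [p.extent[1] for p in grid.patches],
            "extent_z": [p.extent[2] for p in grid.patches],
            "overlap_fraction": [p.brain_overlap_fraction for p in grid.patches],
        }
    )


def save_grid(grid: PatchGrid, path) -> None:
    grid_to_frame(grid).to_csv(path, sep="\t", index=False)


def load_grid(
    path,
    patch_dims_mm: tuple[float, float, float],
    template_shape: tuple[int, int, int],
    overlap_threshold: float = 0.10,
) -> PatchGrid:
    df = pd.read_csv(path, sep="\t")
    patches = [
        Patch(
            patch_id=int(r.patch_id),
            hemisphere=str(r.hemisphere),
            min_corner=(int(r.min_x), int(r.min_y), int(r.min_z)),
            extent=(int(r.extent_x), int(r.extent_y), int(r.extent_z)),
            brain_overlap_fraction=float(r.overlap_fraction),
        )
        for r in df.itertuples()
    ]
    return PatchGrid(
        patch_dims_mm=patch_dims_mm,
        patches=patches,
        template_shape=template_shape,
        overlap_threshold=overlap_threshold,
    )
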