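"""Synthetic template-space cohorts with known class-dependent atrophy.

Real T1 cohorts of this kind are access-controlled, so every downstream
stage is exercised on generated volumes that emulate the *post-preprocessed*
state: skull-stripped, intensity-normalised, co-registered brains sharing
one template mask.  Atrophy is modelled as a multiplicative intensity
reduction inside class-specific patches, applied to a deterministic baseline
tissue pattern before spatially smoothed Gaussian noise is added.  Because
every parameter is known, recovery of the planted patches by the full
pipeline is a ground-truth test.

The brain mask is an ellipsoid with a one-voxel mid-sagittal fissure
separating the hemispheres; a toy atlas labels each patch box as its own
named region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import AtlasLabelVolume, CLASS_LABELS, PatchGrid, VolumeImage
from .parcellation import tile_patches

#: Mean tissue intensity of the baseline pattern (arbitrary normalised units).
BASELINE_INTENSITY = 1.0


@dataclass
class SyntheticCohortSpec:
    """Parameters of a generated cohort.

    ``affected_patches`` maps a class label to the patch ids (in the grid
    derived from ``grid_shape`` and ``patch_dims_mm``) whose mean intensity
    is reduced by the factor ``1 - effect_size`` for subjects of that class.
    Identical spec + seed reproduce byte-identical volumes.
    """

    grid_shape: tuple[int, int, int] = (60, 45, 60)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 20, "MCI": 20, "NC": 20}
    )
    affected_patches: Mapping[str, frozenset] = field(default_factory=dict)
    effect_size: float = 0.3
    noise_sd: float = 0.05
    smoothing_fwhm_mm: float = 2.0
    patch_dims_mm: tuple[float, float, float] = (10.0, 15.0, 20.0)
    overlap_threshold: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("all class counts must be >= 1")
        unknown = set(self.n_per_class) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """Generated volumes plus the shared mask, grid and toy atlas."""

    volumes: list[VolumeImage]
    atlas: AtlasLabelVolume
    mask: np.ndarray
    grid: PatchGrid
    spec: SyntheticCohortSpec


def make_brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal brain mask with a one-voxel mid-sagittal fissure."""
    nx, ny, nz = grid_shape
    center = (np.array(grid_shape) - 1) / 2.0
    semi = 0.47 * np.array(grid_shape)
    x, y, z = np.ogrid[:nx, :ny, :nz]
    r2 = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )
    mask = r2 <= 1.0
    mask[nx // 2, :, :] = False  # medial longitudinal fissure
    return mask


def baseline_pattern(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic smooth tissue-intensity pattern shared by all subjects.

    Low-frequency cosines on scales comparable to the patch size, plus a
    radial brightening toward the centre, so that patch pairs span a wide
    range of |Pearson| values on both sides of the 0.3 link threshold.
    """
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    center = (np.array(grid_shape) - 1) / 2.0
    r2 = (
        ((x - center[0]) / (0.5 * nx)) ** 2
        + ((y - center[1]) / (0.5 * ny)) ** 2
        + ((z - center[2]) / (0.5 * nz)) ** 2
    )
    pattern = (
        BASELINE_INTENSITY
        + 0.054 * np.cos(2 * np.pi * x / 24.0)
        + 0.045 * np.cos(2 * np.pi * y / 18.0)
        + 0.045 * np.cos(2 * np.pi * z / 30.0)
        + 0.030 * np.cos(2 * np.pi * (x + z) / 40.0)
        + 0.060 * np.exp(-2.0 * r2)
    )
    return pattern


def _smoothed_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sd: float,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Gaussian noise with spatial correlation scale ``fwhm_mm``.

    White noise is smoothed by a separable Gaussian kernel, then rescaled so
    the marginal standard deviation equals ``sd`` again (smoothing shrinks
    it); the stated sd is therefore the sd actually present in the volume.
    """
    white = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = [
            fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
            for v in voxel_size_mm
        ]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        s = smooth.std()
        if s > 0:
            smooth = smooth / s
    else:
        smooth = white
    return sd * smooth


def cohort_grid(spec: SyntheticCohortSpec) -> tuple[np.ndarray, PatchGrid]:
    """The shared brain mask and the patch grid it induces."""
    mask = make_brain_mask(spec.grid_shape)
    grid = tile_patches(
        mask,
        spec.patch_dims_mm,
        overlap_threshold=spec.overlap_threshold,
        voxel_size_mm=spec.voxel_size_mm,
    )
    return mask, grid


def make_toy_atlas(grid: PatchGrid, shape: tuple[int, int, int]) -> AtlasLabelVolume:
    """Label volume assigning each patch box its own integer label.

    Label patch_id + 1 (0 is background); names follow
    ``toy_region_<label>``.
    """
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    for p in grid.patches:
        lab = p.patch_id + 1
        labels[p.slices] = lab
        names[lab] = f"toy_region_{lab:03d}"
    return AtlasLabelVolume(labels=labels, name_table=names, background_label=0)


def standard_cohort_spec(
    n_per_class: int = 60,
    effect_size: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticCohortSpec:
    """The package's reference study conditions.

    Balanced classes on the default desk-scale grid, five affected patches
    for each impaired class (disjoint sets, alternating over the low patch
    ids so both hemispheres participate), 30% intensity reduction against
    5% noise.
    """
    return SyntheticCohortSpec(
        n_per_class={"AD": n_per_class, "MCI": n_per_class, "NC": n_per_class},
        affected_patches={
            "AD": frozenset({0, 2, 4, 6, 8}),
            "MCI": frozenset({1, 3, 5, 7, 9}),
        },
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the cohort of volumes plus the toy atlas.

    For a subject of class ``c`` the baseline pattern is multiplied by
    ``1 - effect_size`` inside every patch of ``affected_patches[c]``, then
    smoothed Gaussian noise is added and the result clipped at zero and
    masked.  All randomness descends from ``spec.seed``; a given spec
    reproduces byte-identical volumes.
    """
    mask, grid = cohort_grid(spec)
    n_patches = len(grid)
    for cls, pids in spec.affected_patches.items():
        bad = [p for p in pids if not 0 <= int(p) < n_patches]
        if bad:
            raise ValueError(
                f"affected_patches[{cls!r}] outside the grid's "
                f"0..{n_patches - 1} patch range: {sorted(bad)}"
            )

    base = baseline_pattern(spec.grid_shape)
    atlas = make_toy_atlas(grid, spec.grid_shape)

    ss = np.random.SeedSequence(spec.seed)
    volumes: list[VolumeImage] = []
    for cls in sorted(spec.n_per_class):
        affected = sorted(int(p) for p in spec.affected_patches.get(cls, ()))
        signal = base.copy()
        for pid in affected:
            signal[grid.patches[pid].slices] *= 1.0 - spec.effect_size
        for k in range(spec.n_per_class[cls]):
            rng = np.random.default_rng(ss.spawn(1)[0])
            noise = _smoothed_noise(
                rng,
                spec.grid_shape,
                spec.noise_sd * BASELINE_INTENSITY,
                spec.smoothing_fwhm_mm,
                spec.voxel_size_mm,
            )
            vol = np.clip(signal + noise, 0.0, None)
            vol[~mask] = 0.0
            volumes.append(
                VolumeImage(
                    intensities=vol.astype(np.float32),
                    brain_mask=mask,
                    voxel_size_mm=spec.voxel_size_mm,
                    subject_id=f"{cls}_{k:03d}",
                    class_label=cls,
                )
            )
    return SyntheticCohort(
        volumes=volumes, atlas=atlas, mask=mask, grid=grid, spec=spec
    )
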