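"""Shared fixtures: small synthetic objects used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from patchconn.core import Patch, PatchGrid, SubjectNetwork, VolumeImage
from patchconn.synthetic_cohort import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny cohort with planted atrophy, shared read-only across tests."""
    spec = SyntheticCohortSpec(
        n_per_class={"AD": 6, "MCI": 6, "NC": 6},
        affected_patches={"AD": frozenset({0, 2}), "MCI": frozenset({1, 3})},
        effect_size=0.3,
        noise_sd=0.05,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture()
def odd_ellipsoid_mask():
    """Symmetric ellipsoid on an odd-x grid (exact left/right symmetry)."""
    shape = (21, 15, 17)
    center = (np.array(shape) - 1) / 2
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = (
        ((x - center[0]) / 9) ** 2
        + ((y - center[1]) / 6) ** 2
        + ((z - center[2]) / 7) ** 2
    )
    return r2 <= 1.0


def random_network(rng: np.random.Generator, n: int, density: float = 0.6,
                   threshold: float = 0.3) -> SubjectNetwork:
    """Random symmetric weighted network respecting the weight contract."""
    w = rng.uniform(threshold, 1.0, size=(n, n))
    keep = rng.random((n, n)) < density
    w = np.where(keep, w, 0.0)
    w = np.triu(w, k=1)
    w = w + w.T
    return SubjectNetwork(subject_id="rnd", adjacency=w, node_ids=list(range(n)),
                          threshold=threshold)


def box_grid(n_patches: int, extent=(10, 15, 20)) -> PatchGrid:
    """A synthetic PatchGrid of n disjoint boxes (analytic tests only)."""
    patches = [
        Patch(
            patch_id=i,
            hemisphere="left" if i % 2 == 0 else "right",
            min_corner=(0, 0, i * extent[2]),
            extent=extent,
            brain_overlap_fraction=1.0,
        )
        for i in range(n_patches)
    ]
    return PatchGrid(
        patch_dims_mm=tuple(float(e) for e in extent),
        patches=patches,
        template_shape=(extent[0], extent[1], extent[2] * n_patches),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
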