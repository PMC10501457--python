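"""Per-subject correlation networks over patches.

Each subject's network has one node per patch; the link weight between two
patches is the absolute Pearson correlation of their voxel-intensity
vectors (absolute, so mirrored left/right patterns connect alike).  Weak
links below a threshold (default 0.3) are removed as likely noise.
Networks are built within one subject only — no cross-subject layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PatchGrid, SubjectNetwork, VolumeImage
from .parcellation import extract_patch_matrix

DEFAULT_THRESHOLD = 0.3


def pearson_links(vectors: np.ndarray) -> np.ndarray:
    """Absolute pairwise Pearson correlations of patch vectors.

    Parameters
    ----------
    vectors
        Array of shape (P, L): one row per patch, L voxels each.

    Returns
    -------
    P x P matrix of |r| with zero diagonal.  A patch vector with zero
    variance correlates 0 with everything (rather than raising), keeping the
    per-subject pipeline total on degenerate patches.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be a 2-D array (patches x voxels)")
    if vectors.shape[1] < 2:
        raise ValueError("patch vectors must have length >= 2")
    sd = vectors.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vectors)
    r = np.abs(r)
    r[~np.isfinite(r)] = 0.0
    degenerate = sd == 0
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 0.0)
    return np.clip(r, 0.0, 1.0)


def threshold_network(
    weights: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    subject_id: str = "",
    node_ids=None,
) -> SubjectNetwork:
    """Remove weak links (weight < threshold); weights at the cut survive."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError("weights must be square")
    if not np.allclose(weights, weights.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    if np.any(weights < 0) or np.any(weights > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    adj = np.where(weights < threshold, 0.0, weights)
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 0.0)
    if node_ids is None:
        node_ids = list(range(weights.shape[0]))
    return SubjectNetwork(
        subject_id=subject_id,
        adjacency=adj,
        node_ids=list(node_ids),
        threshold=threshold,
    )


def build_network(
    volume: VolumeImage,
    grid: PatchGrid,
    threshold: float = DEFAULT_THRESHOLD,
) -> SubjectNetwork:
    """Patch extraction -> |Pearson| links -> thresholding, for one subject."""
    vectors = extract_patch_matrix(volume, grid)
    weights = pearson_links(vectors)
    return threshold_network(
        weights,
        threshold=threshold,
        subject_id=volume.subject_id,
        node_ids=grid.patch_ids,
    )


def network_to_edge_frame(net: SubjectNetwork) -> pd.DataFrame:
    """Sparse upper-triangular edge list (node_i, node_j, weight)."""
    i, j = np.nonzero(np.triu(net.adjacency, k=1))
    return pd.DataFrame(
        {
            "node_i": np.asarray(net.node_ids)[i],
            "node_j": np.asarray(net.node_ids)[j],
            "weight": net.adjacency[i, j],
        }
    )


def save_edge_list(net: SubjectNetwork, path) -> None:
    network_to_edge_frame(net).to_csv(path, sep="\t", index=False)


def load_edge_list(path, node_ids, threshold: float, subject_id: str = "") -> SubjectNetwork:
    df = pd.read_csv(path, sep="\t")
    node_ids = list(node_ids)
    index = {nid: k for k, nid in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)))
    for r in df.itertuples():
        a, b = index[int(r.node_i)], index[int(r.node_j)]
        adj[a, b] = adj[b, a] = float(r.weight)
    return SubjectNetwork(
        subject_id=subject_id, adjacency=adj, node_ids=node_ids, threshold=threshold
    )
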