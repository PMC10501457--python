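"""Nodal centralities and the cohort feature matrix.

Three complementary centralities summarise each patch's role in a subject's
network: strength (local; sum of incident edge weights), betweenness
(dynamic; fraction of all-pairs shortest paths through the node, with edge
distance 1/weight so stronger correlations are shorter) and eigenvector
centrality (global; the dominant eigenvector of the weighted adjacency).
Stacking the three per-node metrics for every subject yields the M x 3P
feature matrix that the classification stage consumes.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .core import FeatureMatrix, PatchGrid, SubjectNetwork, feature_name

logger = logging.getLogger(__name__)


def strength(net: SubjectNetwork) -> np.ndarray:
    """Sum of edge weights at each node (adjacency row sums)."""
    return net.adjacency.sum(axis=1)


def betweenness(net: SubjectNetwork, normalized: bool = True) -> np.ndarray:
    """Weighted betweenness centrality with the 1/w distance transform.

    Shortest paths minimise the sum of inverse weights, so paths through
    strong correlations are short.  With ``normalized`` the count of
    shortest paths through a node is divided by (P-1)(P-2)/2, bounding the
    feature in [0, 1] regardless of network size.  Disconnected pairs
    contribute nothing.
    """
    adj = net.adjacency
    g = nx.from_numpy_array(adj)
    for _, _, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    bc = nx.betweenness_centrality(g, weight="distance", normalized=normalized)
    return np.array([bc[i] for i in range(net.n_nodes)])


def eigenvector_centrality(net: SubjectNetwork) -> np.ndarray:
    """Dominant (Perron) eigenvector of the weighted adjacency, unit norm.

    Nodes outside the spectrally dominant component come out (numerically)
    zero.  The sign is fixed by making the largest-magnitude entry positive;
    tiny negative round-off is clipped.  An edgeless network yields all
    zeros with a logged warning.
    """
    adj = net.adjacency
    if not np.any(adj):
        logger.warning(
            "subject %s: edgeless network, eigenvector centrality is all-zero",
            net.subject_id,
        )
        return np.zeros(net.n_nodes)
    vals, vecs = np.linalg.eigh(adj)
    v = vecs[:, np.argmax(vals)]
    v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def node_metrics(net: SubjectNetwork) -> dict[str, np.ndarray]:
    """All three centralities for one subject, keyed by metric name."""
    return {
        "strength": strength(net),
        "betweenness": betweenness(net),
        "eigenvector": eigenvector_centrality(net),
    }


def assemble_features(
    nets: list[SubjectNetwork],
    grid: PatchGrid,
    labels: list[str],
) -> FeatureMatrix:
    """Stack per-subject nodal metrics into the cohort feature matrix.

    Columns are ordered metric-major: all strengths in patch order, then all
    betweenness, then all eigenvector centralities (n = 3P columns).
    """
    if not nets:
        raise ValueError("no networks given")
    if len(labels) != len(nets):
        raise ValueError("labels length must match number of networks")
    ids = grid.patch_ids
    for net in nets:
        if list(net.node_ids) != ids:
            raise ValueError(
                f"subject {net.subject_id}: node ids do not match the grid"
            )
    names = [
        feature_name(metric, pid)
        for metric in ("strength", "betweenness", "eigenvector")
        for pid in ids
    ]
    rows = []
    for net in nets:
        m = node_metrics(net)
        rows.append(
            np.concatenate([m["strength"], m["betweenness"], m["eigenvector"]])
        )
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=list(labels),
        subject_ids=[n.subject_id for n in nets],
    )
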