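"""Interventional Shapley-value estimators.

The value of a coalition S for an input x is the model output with the
features in S fixed at x and the rest marginalised over a background
sample: v(S) = mean_z f(x_S, z_{S~}).  Attributions are computed exactly by
enumerating all 2^d coalitions when the feature count d is small — which
the pipeline's feature-selection stage guarantees — and otherwise by a
seeded permutation-sampling estimator.  Both routes satisfy the efficiency
axiom exactly (the per-permutation marginals telescope), so
baseline + sum(phi) equals the model output f(x) to round-off.
"""

from __future__ import annotations

import numpy as np

#: Largest feature count for which coalitions are enumerated exhaustively.
EXACT_LIMIT = 13


def _coalition_values(
    predict,
    x_rows: np.ndarray,
    background: np.ndarray,
    masks: np.ndarray,
    batch_rows: int = 200_000,
) -> np.ndarray:
    """v(S) for each mask (rows) and each explain row (columns).

    ``masks`` is (n_masks, d) boolean; returns (n_masks, m).
    """
    m, d = x_rows.shape
    nb = background.shape[0]
    out = np.empty((len(masks), m))
    per_mask = m * nb
    chunk = max(1, batch_rows // per_mask)
    for start in range(0, len(masks), chunk):
        block = masks[start : start + chunk]
        rows = np.empty((len(block), m, nb, d))
        rows[:] = background[None, None, :, :]
        for k, mask in enumerate(block):
            rows[k, :, :, mask] = x_rows[:, mask].T[:, :, None]
        preds = np.asarray(predict(rows.reshape(-1, d)), dtype=float)
        out[start : start + len(block)] = preds.reshape(len(block), m, nb).mean(
            axis=2
        )
    return out


def exact_shapley(
    predict,
    x_rows: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exhaustive-coalition Shapley values for each row of ``x_rows``.

    Returns (phi, baseline) with phi of shape (m, d); baseline is the mean
    model output over the background, shared by all rows.
    """
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m, d = x_rows.shape
    if d > EXACT_LIMIT:
        raise ValueError(
            f"exact enumeration limited to {EXACT_LIMIT} features (got {d})"
        )
    n_masks = 1 << d
    bit = 1 << np.arange(d)
    all_masks = (np.arange(n_masks)[:, None] & bit[None, :]) > 0
    v = _coalition_values(predict, x_rows, background, all_masks)
    sizes = all_masks.sum(axis=1)
    from math import factorial

    w = np.array(
        [factorial(s) * factorial(d - 1 - s) / factorial(d) for s in range(d)]
    )
    phi = np.zeros((m, d))
    for mask_index in range(n_masks):
        s = sizes[mask_index]
        for i in range(d):
            if not all_masks[mask_index, i]:
                with_i = mask_index | (1 << i)
                phi[:, i] += w[s] * (v[with_i] - v[mask_index])
    baseline = float(v[0].mean())  # v(empty) is identical for every row
    return phi, baseline


def sampled_shapley(
    predict,
    x_rows: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 128,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimator (antithetic, seeded).

    Each sampled feature order contributes the marginal effect of adding
    features one at a time; orders are drawn in antithetic pairs (a random
    order and its reverse) to cut variance.  Efficiency holds exactly for
    any number of permutations.
    """
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m, d = x_rows.shape
    rng = np.random.default_rng(seed)
    orders = []
    for _ in range((n_permutations + 1) // 2):
        p = rng.permutation(d)
        orders.append(p)
        orders.append(p[::-1])
    orders = orders[:n_permutations]
    phi = np.zeros((m, d))
    baseline = None
    for order in orders:
        masks = np.zeros((d + 1, d), dtype=bool)
        for k, feat in enumerate(order):
            masks[k + 1] = masks[k]
            masks[k + 1, feat] = True
        v = _coalition_values(predict, x_rows, background, masks)
        if baseline is None:
            baseline = float(v[0].mean())
        for k, feat in enumerate(order):
            phi[:, feat] += v[k + 1] - v[k]
    phi /= len(orders)
    return phi, baseline


def shapley_values(
    predict,
    x_rows: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 128,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Exact enumeration when feasible, sampling otherwise."""
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    if x_rows.shape[1] <= EXACT_LIMIT:
        return exact_shapley(predict, x_rows, background)
    return sampled_shapley(
        predict, x_rows, background, n_permutations=n_permutations, seed=seed
    )
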