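"""Fast class-probability evaluation for fitted sklearn forests.

Shapley value functions evaluate the model on very large batches of
background-mixed rows; going through per-tree leaf tables with direct
``tree_.apply`` calls avoids per-call estimator overhead while producing
exactly the probabilities ``predict_proba`` would (mean of per-tree leaf
class frequencies).
"""

from __future__ import annotations

import numpy as np


class ForestEvaluator:
    """Callable returning class probabilities for a fitted forest."""

    def __init__(self, forest):
        self.forest = forest
        self.values = []
        for est in forest.estimators_:
            v = est.tree_.value[:, 0, :]
            v = v / np.clip(v.sum(axis=1, keepdims=True), 1e-12, None)
            self.values.append(v)
        self.n_classes = self.values[0].shape[1]

    def proba(self, X: np.ndarray) -> np.ndarray:
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        agg = np.zeros((X32.shape[0], self.n_classes))
        for est, v in zip(self.forest.estimators_, self.values):
            agg += v[est.tree_.apply(X32)]
        return agg / len(self.values)

    def class_score(self, class_index: int):
        """Scalar-output predictor: probability of one class."""

        def predict(X: np.ndarray) -> np.ndarray:
            return self.proba(X)[:, class_index]

        return predict
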