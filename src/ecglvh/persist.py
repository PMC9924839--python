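"""JSON persistence for fitted LVH models.

Models are stored as plain JSON (weights, normalisation statistics,
configuration) so a saved model is diffable and loadable without
pickle.  Loading returns a lightweight predictor implementing
``predict`` and ``evaluate`` with a NumPy forward pass.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import BpnResults, DecisionTreeResults, KMeansResults, ModelReport


class _JsonPredictor:
    """Shared prediction surface for models restored from JSON."""

    def __init__(self, payload: dict):
        self.payload = payload
        self.kind = payload["kind"]
        self.feature_names = payload["feature_names"]

    def _matrix(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if set(self.feature_names).issubset(X.columns):
            X = X[self.feature_names]
        return X.to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        arr = self._matrix(X)
        if self.kind == "bpn":
            return self._predict_bpn(arr)
        if self.kind == "tree":
            return self._predict_tree(arr)
        if self.kind == "kmeans":
            return self._predict_kmeans(arr)
        raise ValueError(f"unknown model kind {self.kind!r}")

    def evaluate(self, X, y) -> ModelReport:
        return ModelReport.from_predictions(np.asarray(y).astype(bool), self.predict(X))

    # --- per-kind forward passes -------------------------------------

    def _predict_bpn(self, arr: np.ndarray) -> np.ndarray:
        p = self.payload
        z = (arr - np.array(p["norm_mean"])) / np.array(p["norm_sd"])
        a = z
        n_layers = len(p["weights"])
        for i, (W, b) in enumerate(zip(p["weights"], p["biases"])):
            a = a @ np.array(W) + np.array(b)
            if i < n_layers - 1:
                a = _activate(a, p["activation"])
            else:
                a = 1.0 / (1.0 + np.exp(-a))  # sigmoid output unit
        return (a.ravel() > 0.5)

    def _predict_tree(self, arr: np.ndarray) -> np.ndarray:
        p = self.payload["tree"]
        left = p["children_left"]
        right = p["children_right"]
        feat = p["feature"]
        thr = p["threshold"]
        value = p["value"]  # [n_nodes][2] class counts (neg, pos)
        out = np.empty(arr.shape[0], dtype=bool)
        for i, row in enumerate(arr):
            node = 0
            while left[node] != -1:
                node = left[node] if row[feat[node]] <= thr[node] else right[node]
            neg, pos = value[node]
            out[i] = pos > neg
        return out

    def _predict_kmeans(self, arr: np.ndarray) -> np.ndarray:
        centroids = np.array(self.payload["centroids"])
        labels = self.payload["cluster_labels"]
        d = ((arr[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return np.array([labels[int(c)] for c in d.argmin(axis=1)], dtype=bool)


def _activate(a: np.ndarray, name: str) -> np.ndarray:
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-a))
    if name == "tanh":
        return np.tanh(a)
    if name == "relu":
        return np.maximum(a, 0.0)
    if name == "identity":
        return a
    raise ValueError(f"unknown activation {name!r}")


def results_to_json(results) -> dict:
    """Serialise a fitted results object to a JSON-ready dict."""
    feature_names = [str(c) for c in results.model.exog.columns]
    if isinstance(results, BpnResults):
        net = results.estimator
        cfg = results.diagnostics["config"]
        return {
            "kind": "bpn",
            "feature_names": feature_names,
            "activation": cfg.activation,
            "weights": [w.tolist() for w in net.coefs_],
            "biases": [b.tolist() for b in net.intercepts_],
            "norm_mean": results.norm_stats["mean"].tolist(),
            "norm_sd": results.norm_stats["sd"].tolist(),
            "config": {
                "hidden_layers": list(cfg.hidden_layers),
                "epochs": cfg.epochs,
                "learning_rate": cfg.learning_rate,
                "batch_size": cfg.batch_size,
                "seed": cfg.seed,
            },
        }
    if isinstance(results, DecisionTreeResults):
        tree = results.estimator.tree_
        return {
            "kind": "tree",
            "feature_names": feature_names,
            "depth": results.depth_,
            "tree": {
                "children_left": tree.children_left.tolist(),
                "children_right": tree.children_right.tolist(),
                "feature": tree.feature.tolist(),
                "threshold": tree.threshold.tolist(),
                "value": tree.value[:, 0, :].tolist(),
            },
        }
    if isinstance(results, KMeansResults):
        return {
            "kind": "kmeans",
            "feature_names": feature_names,
            "centroids": results.estimator.kmeans.cluster_centers_.tolist(),
            "cluster_labels": [
                bool(results.cluster_labels_[c])
                for c in range(len(results.cluster_labels_))
            ],
        }
    raise TypeError(f"cannot serialise {type(results).__name__}")


def save_model(results, path) -> None:
    Path(path).write_text(json.dumps(results_to_json(results)))


def load_model(path) -> _JsonPredictor:
    return _JsonPredictor(json.loads(Path(path).read_text()))
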