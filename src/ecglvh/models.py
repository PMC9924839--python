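"""Classification protocol for LVH detection from the 24 ECG features.

Three model families are exposed as statsmodels-style model classes: an
entropy decision tree with a cross-validated depth search
(:class:`DecisionTreeLVH`), a k-means++ clustering-as-classifier
(:class:`KMeansLVH`), and a back-propagation neural network with one
26-node hidden layer (:class:`BackpropNetLVH`).  Each is constructed
from data, and ``fit()`` returns a results object carrying the fitted
estimator, cross-validation diagnostics, ``predict``/``evaluate``
methods, and a ``summary()`` table.

The evaluation protocol mirrors the study design: class-balanced
cohorts, a 7:3 train:test split, tenfold cross-validation during model
selection, and confusion-matrix metrics with LVH as the positive
class.  When training on beat-level rows, splits are grouped by
subject by default so no subject spans train and test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, zscore_fit_apply

__all__ = [
    "node_entropy",
    "ModelReport",
    "SplitPlan",
    "BpnConfig",
    "balanced_cohort",
    "split_cases",
    "DecisionTreeLVH",
    "KMeansLVH",
    "BackpropNetLVH",
    "LVHResults",
]


def node_entropy(p: float) -> float:
    """Binary entropy of a tree node, in bits.

    ``p`` is the fraction of positive cases in the node and ``q = 1-p``;
    the value is ``-p*log2(p) - q*log2(q)`` with the ``0*log(0) = 0``
    convention.  A pure node scores 0 (ideal split); a half-and-half
    node scores 1 (least informative).
    """
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    q = 1.0 - p
    h = 0.0
    if p > 0.0:
        h -= p * math.log2(p)
    if q > 0.0:
        h -= q * math.log2(q)
    return h


@dataclass(frozen=True)
class ModelReport:
    """Confusion counts and derived metrics, LVH = positive class.

    Ratios with zero denominators are reported as NaN, never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ModelReport":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class SplitPlan:
    """Train/test and cross-validation layout.

    ``balanced`` draws equal class counts before splitting;
    ``grouped`` keeps all rows of one subject on the same side of the
    split (matters only for beat-level tables).
    """

    train_fraction: float = 0.7
    cv_folds: int = 10
    seed: int = 0
    balanced: bool = True
    grouped: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class BpnConfig:
    """Architecture and training hyper-parameters of the network.

    Defaults: 24 inputs, one hidden layer of 26 logistic units, one
    sigmoid output thresholded at 0.5, 400 epochs of mini-batch
    gradient descent (batch 32, learning rate 0.01).  Where the
    protocol leaves details open these are this package's choices.
    """

    n_input: int = 24
    hidden_layers: tuple[int, ...] = (26,)
    n_output: int = 1
    epochs: int = 400
    learning_rate: float = 0.01
    batch_size: int = 32
    activation: str = "logistic"
    seed: int = 0


def balanced_cohort(df: pd.DataFrame, label_col: str = "label", seed: int = 0) -> pd.DataFrame:
    """All minority-class rows plus an equal-size seeded sample of the majority.

    An already balanced input is returned unchanged (up to order).
    """
    labels = df[label_col].astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance a cohort")
    if n_pos == n_neg:
        return df.copy()
    minority = labels if n_pos < n_neg else ~labels
    rng = np.random.default_rng(seed)
    majority_idx = df.index[~minority].to_numpy()
    keep = rng.choice(majority_idx, size=min(n_pos, n_neg), replace=False)
    out = pd.concat([df.loc[df.index[minority]], df.loc[np.sort(keep)]])
    return out.sort_index()


def split_cases(
    df: pd.DataFrame,
    plan: SplitPlan,
    label_col: str = "label",
    group_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """7:3-style train/test split, optionally balanced and subject-grouped."""
    if plan.balanced:
        if group_col is not None:
            # balance at the subject level, then expand back to rows
            per_subject = df.groupby(group_col)[label_col].first().reset_index()
            kept = balanced_cohort(per_subject, label_col, seed=plan.seed)
            df = df[df[group_col].isin(kept[group_col])]
        else:
            df = balanced_cohort(df, label_col, seed=plan.seed)
    if group_col is not None and plan.grouped:
        splitter = GroupShuffleSplit(
            n_splits=1, train_size=plan.train_fraction, random_state=plan.seed
        )
        train_idx, test_idx = next(splitter.split(df, groups=df[group_col]))
        return df.iloc[train_idx], df.iloc[test_idx]
    train, test = train_test_split(
        df,
        train_size=plan.train_fraction,
        random_state=plan.seed,
        stratify=df[label_col],
    )
    return train, test


class BaseLVHModel:
    """Shared container: feature matrix, boolean labels, optional groups."""

    def __init__(self, X, y, groups=None):
        X = pd.DataFrame(X)
        if X.empty:
            raise ValueError("empty feature matrix")
        if not np.all(np.isfinite(X.to_numpy(dtype=float))):
            raise ValueError("feature matrix contains non-finite values")
        y = np.asarray(y).astype(bool)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.exog = X.reset_index(drop=True)
        self.endog = y
        self.groups = None if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_cols=None,
        group_col: str | None = None,
        **kwargs,
    ):
        """Build a model from a tidy table with a label column."""
        if feature_cols is None:
            feature_cols = [c for c in FEATURE_NAMES if c in df.columns]
            if not feature_cols:
                feature_cols = [
                    c
                    for c in df.columns
                    if c not in (label_col, group_col)
                    and pd.api.types.is_numeric_dtype(df[c])
                ]
        groups = df[group_col].to_numpy() if group_col is not None else None
        return cls(df[feature_cols], df[label_col], groups=groups, **kwargs)

    def _check_cv(self, folds: int) -> None:
        n_pos = int(self.endog.sum())
        n_neg = int((~self.endog).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("training set contains a single class")
        if min(n_pos, n_neg) < folds:
            raise ValueError(
                f"{folds}-fold CV needs >= {folds} rows per class; "
                f"got {n_pos} positive / {n_neg} negative"
            )

    def _cv_accuracies(self, make_estimator, plan: SplitPlan) -> np.ndarray:
        """Mean held-out accuracy per fold under stratified k-fold CV."""
        cv = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
        X = self.exog.to_numpy(dtype=float)
        accs = []
        for train_idx, test_idx in cv.split(X, self.endog):
            est = make_estimator()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X[train_idx], self.endog[train_idx])
            accs.append(float(est.score(X[test_idx], self.endog[test_idx])))
        return np.array(accs)


class LVHResults:
    """Fitted-model results: predictions, evaluation, summary."""

    model_name = "LVH model"

    def __init__(self, model: BaseLVHModel, estimator, diagnostics: dict | None = None):
        self.model = model
        self.estimator = estimator
        self.diagnostics = diagnostics or {}

    def _prepare(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        cols = list(self.model.exog.columns)
        if set(cols).issubset(X.columns):
            X = X[cols]
        return X.to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._prepare(X))).astype(bool)

    def evaluate(self, X, y) -> ModelReport:
        if len(pd.DataFrame(X)) == 0:
            raise ValueError("test set is empty")
        return ModelReport.from_predictions(np.asarray(y).astype(bool), self.predict(X))

    def _summary_rows(self) -> list[tuple[str, object]]:
        n = len(self.model.endog)
        rows = [
            ("Model", self.model_name),
            ("No. observations", n),
            ("Positive (LVH)", int(self.model.endog.sum())),
            ("Negative", int(n - self.model.endog.sum())),
            ("Features", self.model.exog.shape[1]),
        ]
        cv = self.diagnostics.get("cv_accuracies")
        if cv is not None:
            rows.append(("CV accuracy (mean ± sd)", f"{np.mean(cv):.3f} ± {np.std(cv):.3f}"))
        return rows

    def summary(self) -> str:
        rows = self._summary_rows()
        width = max(len(k) for k, _ in rows)
        lines = ["=" * (width + 30)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append("=" * (width + 30))
        return "\n".join(lines)


class DecisionTreeResults(LVHResults):
    model_name = "Entropy decision tree"

    @property
    def depth_(self) -> int:
        return self.diagnostics["depth"]

    @property
    def depth_scores_(self) -> pd.DataFrame:
        return self.diagnostics["depth_scores"]

    def _summary_rows(self):
        rows = super()._summary_rows()
        rows.insert(1, ("Chosen depth", self.depth_))
        return rows


class DecisionTreeLVH(BaseLVHModel):
    """Entropy-split decision tree with a cross-validated depth search.

    Depths 1..25 are scored by mean tenfold-CV accuracy on the training
    data; the best depth wins (smallest on ties, for parsimony) and the
    final tree is refit on all training rows at that depth.
    """

    def __init__(self, X, y, groups=None, seed: int = 0):
        super().__init__(X, y, groups=groups)
        self.seed = seed

    def fit(self, depth_range=range(1, 26), cv: SplitPlan | None = None) -> DecisionTreeResults:
        plan = cv or SplitPlan(seed=self.seed)
        self._check_cv(plan.cv_folds)
        records = []
        best_depth, best_mean = None, -np.inf
        for depth in depth_range:
            accs = self._cv_accuracies(
                lambda depth=depth: DecisionTreeClassifier(
                    criterion="entropy", max_depth=depth, random_state=self.seed
                ),
                plan,
            )
            mean = float(np.mean(accs))
            records.append({"depth": depth, "cv_accuracy": mean, "cv_sd": float(np.std(accs))})
            if mean > best_mean:  # strict: first (smallest) depth wins ties
                best_depth, best_mean = depth, mean
        final = DecisionTreeClassifier(
            criterion="entropy", max_depth=best_depth, random_state=self.seed
        )
        final.fit(self.exog.to_numpy(dtype=float), self.endog)
        return DecisionTreeResults(
            self,
            final,
            {
                "depth": int(best_depth),
                "cv_accuracies": np.array([best_mean]),
                "depth_scores": pd.DataFrame(records),
            },
        )


class _KMeansPredictor:
    """Nearest-centroid classifier over a fitted k-means clustering."""

    def __init__(self, kmeans: KMeans, label_map: dict[int, bool]):
        self.kmeans = kmeans
        self.label_map = label_map

    def predict(self, X):
        clusters = self.kmeans.predict(np.asarray(X, dtype=float))
        return np.array([self.label_map[int(c)] for c in clusters], dtype=bool)


class KMeansResults(LVHResults):
    model_name = "k-means++ classifier"

    @property
    def cluster_labels_(self) -> dict[int, bool]:
        return self.estimator.label_map

    def _summary_rows(self):
        rows = super()._summary_rows()
        rows.insert(1, ("Clusters", len(self.cluster_labels_)))
        rows.insert(2, ("Inertia", f"{self.diagnostics['inertia']:.3f}"))
        return rows


class KMeansLVH(BaseLVHModel):
    """k-means++ clustering used as a classifier.

    Lloyd iterations run to convergence from k-means++ seeds; each
    cluster is then mapped to the majority training label among its
    members and prediction is nearest-centroid lookup.
    """

    def __init__(self, X, y, groups=None, seed: int = 0):
        super().__init__(X, y, groups=groups)
        self.seed = seed

    def fit(self, k: int = 2) -> KMeansResults:
        n = len(self.exog)
        if k > n:
            raise ValueError(f"k={k} exceeds {n} training rows")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=self.seed)
        assignments = km.fit_predict(self.exog.to_numpy(dtype=float))
        overall_majority = bool(self.endog.sum() * 2 >= len(self.endog))
        label_map: dict[int, bool] = {}
        for c in range(k):
            members = self.endog[assignments == c]
            if members.size == 0:
                label_map[c] = overall_majority
            else:
                pos = int(members.sum())
                neg = members.size - pos
                label_map[c] = pos > neg or (pos == neg and overall_majority)
        return KMeansResults(
            self,
            _KMeansPredictor(km, label_map),
            {"inertia": float(km.inertia_), "cluster_sizes": np.bincount(assignments, minlength=k)},
        )


class BpnResults(LVHResults):
    model_name = "Back-propagation network (24-26-1)"

    def __init__(self, model, estimator, diagnostics, norm_stats):
        super().__init__(model, estimator, diagnostics)
        self.norm_stats = norm_stats

    def _prepare(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        cols = list(self.model.exog.columns)
        if set(cols).issubset(X.columns):
            X = X[cols]
        arr = X.to_numpy(dtype=float)
        mean = self.norm_stats["mean"].to_numpy()
        sd = self.norm_stats["sd"].to_numpy()
        return (arr - mean) / sd

    def _summary_rows(self):
        rows = super()._summary_rows()
        cfg = self.diagnostics["config"]
        rows.insert(1, ("Hidden layers", cfg.hidden_layers))
        rows.insert(2, ("Epochs", cfg.epochs))
        rows.append(("Final training loss", f"{self.diagnostics['loss']:.4f}"))
        return rows


class BackpropNetLVH(BaseLVHModel):
    """Feed-forward network trained by back-propagation.

    Features are z-scored with statistics fitted on the training rows;
    the network is one hidden layer of 26 logistic units and a sigmoid
    output thresholded at 0.5.  ``fit`` optionally reports tenfold-CV
    accuracy before refitting on all training rows.
    """

    def __init__(self, X, y, groups=None, config: BpnConfig | None = None):
        super().__init__(X, y, groups=groups)
        self.config = config or BpnConfig()

    def _make_estimator(self, standardize: bool = False):
        cfg = self.config
        net = MLPClassifier(
            hidden_layer_sizes=tuple(cfg.hidden_layers),
            activation=cfg.activation,
            solver="sgd",
            momentum=0.0,
            nesterovs_momentum=False,
            learning_rate_init=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_iter=cfg.epochs,
            n_iter_no_change=max(cfg.epochs, 10),
            tol=0.0,
            shuffle=True,
            random_state=cfg.seed,
        )
        if standardize:
            return Pipeline([("zscore", StandardScaler()), ("net", net)])
        return net

    def fit(self, cv: SplitPlan | None = None) -> BpnResults:
        cv_accs = None
        if cv is not None:
            self._check_cv(cv.cv_folds)
            cv_accs = self._cv_accuracies(lambda: self._make_estimator(standardize=True), cv)
        else:
            self._check_cv(2)
        X_z, _, stats = zscore_fit_apply(self.exog)
        net = self._make_estimator(standardize=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(X_z.to_numpy(dtype=float), self.endog)
        if not math.isfinite(net.loss_):
            raise RuntimeError(
                f"training diverged (loss={net.loss_}); inputs z-scored? "
                f"learning rate {self.config.learning_rate} too large?"
            )
        diagnostics = {
            "config": self.config,
            "loss": float(net.loss_),
            "loss_curve": np.asarray(net.loss_curve_),
        }
        if cv_accs is not None:
            diagnostics["cv_accuracies"] = cv_accs
        return BpnResults(self, net, diagnostics, stats)
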