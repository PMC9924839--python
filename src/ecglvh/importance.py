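"""Feature importance by one-way ANOVA F-statistic and elimination curves.

The F-statistic of a feature is the ratio of between-group variance to
within-group variance across the LVH and non-LVH groups:

    F = [sum_g n_g (m_g - m)^2 / (G - 1)] / [sum_g sum_h (x_gh - m_g)^2 / (n - G)]

Large values mark features whose class means separate well relative to
their spread.  Ranking features by F and then retraining while dropping
the weakest feature one at a time yields an accuracy-versus-k curve
that shows how many amplitudes the classifier actually needs.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import BpnConfig, BackpropNetLVH, SplitPlan, split_cases


def f_statistic(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA F over two or more sample groups.

    Returns ``inf`` when the within-group variance is zero but the
    group means differ, and ``nan`` when both variances are zero.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    G = len(arrays)
    if G < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    n = sum(a.size for a in arrays)
    if n <= G:
        raise ValueError(f"need total n > G, got n={n}, G={G}")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    msb = ssb / (G - 1)
    msw = ssw / (n - G)
    if msw == 0.0:
        return float("inf") if msb > 0.0 else float("nan")
    return float(msb / msw)


def rank_features(X: pd.DataFrame, y) -> pd.DataFrame:
    """Per-feature two-group F values, sorted descending.

    Ties keep the input (canonical) column order.  Returns a DataFrame
    with columns ``feature`` and ``F``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to rank features")
    rows = [
        {"feature": col, "F": f_statistic([X.loc[y, col], X.loc[~y, col]])}
        for col in X.columns
    ]
    table = pd.DataFrame(rows)
    order = np.argsort(-table["F"].to_numpy(), kind="stable")
    return table.iloc[order].reset_index(drop=True)


def _default_factory(X, y):
    return BackpropNetLVH(X, y, config=BpnConfig()).fit()


def elimination_curve(
    X: pd.DataFrame,
    y,
    model_factory: Callable | None = None,
    plan: SplitPlan | None = None,
    rerank: bool = False,
) -> pd.DataFrame:
    """Accuracy as the weakest features are dropped one at a time.

    A single train/test split (from ``plan``) is reused for every
    feature count so the points are comparable.  The F-ranking is
    computed once on the training rows; with ``rerank=True`` it is
    recomputed after each removal instead.

    Returns a DataFrame with columns ``n_features`` and ``accuracy``,
    from the full feature set down to one.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y).astype(bool)
    plan = plan or SplitPlan()
    factory = model_factory or _default_factory

    df = X.copy()
    df["label"] = y
    train, test = split_cases(df, plan)
    feat_cols = list(X.columns)
    ranking = list(rank_features(train[feat_cols], train["label"])["feature"])

    records = []
    kept = list(ranking)
    for k in range(len(feat_cols), 0, -1):
        kept = kept[:k]
        results = factory(train[kept], train["label"].to_numpy())
        report = results.evaluate(test[kept], test["label"].to_numpy())
        records.append({"n_features": k, "accuracy": report.accuracy})
        if rerank and k > 1:
            kept = list(rank_features(train[kept], train["label"])["feature"])
    return pd.DataFrame(records)
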