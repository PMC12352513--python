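"""Which scene factor drives predicted discriminability?

Random-forest variance-reduction importances over the categorical design
factors (lighting, shape, viewpoint), per-level descriptive bounds of the
discriminability scores, and percentile-based scene selection for follow-up
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.preprocessing import OneHotEncoder

__all__ = ["ImportanceReport", "rf_importance", "per_level_stats", "percentile_scene"]


@dataclass
class ImportanceReport:
    importances: dict  # factor -> normalized impurity importance
    permutation_importances: dict  # cross-check, not normalized
    ranking: list[str]  # factors, most important first
    per_level: pd.DataFrame  # factor, level, mean, sd, n


def rf_importance(design: pd.DataFrame, scores: np.ndarray,
                  n_trees: int = 500, seed: int = 0,
                  permutation: bool = True) -> ImportanceReport:
    """Normalized per-factor importance of the design columns for the scores.

    Factors are one-hot encoded; each factor's importance is the sum of its
    dummy columns' impurity importances, normalized to sum to 1 across
    factors.  Permutation importances (5 repeats) are included as an
    independent cross-check.  Constant scores carry no signal: all
    importances are 0 and a warning is raised.
    """
    scores = np.asarray(scores, float)
    if len(design) != len(scores):
        raise ValueError("one score per scene required")
    for col in design.columns:
        if design[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
    factors = list(design.columns)
    per_level = per_level_stats(design, scores)

    if scores.std() < 1e-15:
        warnings.warn("constant scores: importances undefined, returning zeros")
        zeros = {f: 0.0 for f in factors}
        return ImportanceReport(zeros, dict(zeros), factors, per_level)

    enc = OneHotEncoder(sparse_output=False)
    X = enc.fit_transform(design.astype(str))
    groups = np.concatenate([[i] * len(c) for i, c in enumerate(enc.categories_)])
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, scores)
    imp = np.array([rf.feature_importances_[groups == i].sum()
                    for i in range(len(factors))])
    imp = imp / imp.sum() if imp.sum() > 0 else imp
    if permutation:
        perm = permutation_importance(rf, X, scores, n_repeats=5, random_state=seed)
        perm_by_factor = {f: float(perm.importances_mean[groups == i].sum())
                          for i, f in enumerate(factors)}
    else:
        perm_by_factor = {}
    ranking = [factors[i] for i in np.argsort(imp)[::-1]]
    return ImportanceReport(dict(zip(factors, imp.tolist())), perm_by_factor,
                            ranking, per_level)


def per_level_stats(design: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Mean, SD and count of the scores at every level of every factor."""
    scores = np.asarray(scores, float)
    rows = []
    for col in design.columns:
        for level, idx in design.groupby(col, sort=True).groups.items():
            vals = scores[design.index.get_indexer(idx)]
            rows.append({"factor": col, "level": level,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=0)),
                         "n": len(vals)})
    return pd.DataFrame(rows)


def percentile_scene(scores: np.ndarray, q: float,
                     scene_ids=None, convention: str = "nearest") -> int | str:
    """Scene whose score is nearest the q-th percentile of the distribution.

    ``convention='nearest'`` (default) picks the scene closest to the
    linear-interpolation percentile value; ``'bin'`` picks the lowest-id
    scene inside the decile bin containing q.  Ties break toward the
    smaller scene id.
    """
    scores = np.asarray(scores, float)
    if scores.size < 10:
        raise ValueError("need at least 10 scenes")
    ids = np.arange(scores.size) if scene_ids is None else np.asarray(scene_ids)
    if convention == "nearest":
        target = np.percentile(scores, q)  # linear interpolation
        dist = np.abs(scores - target)
        best = dist.min()
        cand = np.where(dist <= best + 1e-15)[0]
    elif convention == "bin":
        lo, hi = np.percentile(scores, [10 * (q // 10), min(10 * (q // 10) + 10, 100)])
        cand = np.where((scores >= lo) & (scores <= hi))[0]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    order = np.lexsort((ids[cand],))
    return ids[cand[order[0]]]
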