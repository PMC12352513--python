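"""Aggregation and modelling of pairs-of-pairs gloss judgments.

Participants repeatedly choose which of two scenes shows the larger apparent
gloss difference.  This module turns those trials into per-scene selection
frequencies, applies the quality gates (practice accuracy >= 90%; exclusion
of observers whose mean correlation with the rest falls below the lower
Tukey fence Q1 - 1.5*IQR), pools the kept observers, and relates image-metric
predictors to the pooled choice proportions by Pearson correlation, a
binomial GLM on (chosen, opportunities), and a z-scored cue-combination
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SelectionFrequencies",
    "ExclusionReport",
    "practice_gate",
    "selection_frequencies",
    "exclude_outliers",
    "pool_frequencies",
    "correlate",
    "fit_glm",
    "fit_zscored_combo",
]


@dataclass
class SelectionFrequencies:
    """Per-participant selection counts over scenes."""

    participants: list[str]
    counts: np.ndarray  # (n_participants, n_scenes)
    opportunities: np.ndarray  # (n_participants, n_scenes)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / np.clip(self.opportunities, 1, None)


@dataclass
class ExclusionReport:
    participants: list[str]
    mean_correlation: np.ndarray
    fence: float
    excluded: np.ndarray  # boolean
    reasons: dict


def practice_gate(n_correct: int, n_trials: int, threshold: float = 0.90) -> bool:
    """Pass iff practice accuracy >= threshold (defaults to the 90% gate)."""
    if n_trials <= 0:
        raise ValueError("need at least one practice trial")
    return n_correct / n_trials >= threshold


def practice_gate_from_trials(trials: pd.DataFrame, threshold: float = 0.90) -> dict:
    """Apply the gate per participant; practice trials encode the correct
    answer as item_a (larger planted difference first)."""
    out = {}
    practice = trials[trials["phase"] == "practice"]
    for pid, grp in practice.groupby("participant_id"):
        out[pid] = practice_gate(int((grp["choice"] == grp["item_a"]).sum()),
                                 len(grp), threshold)
    return out


def selection_frequencies(trials: pd.DataFrame, n_scenes: int) -> SelectionFrequencies:
    """Count, per participant, how often each scene was chosen and how often
    it was on offer.  Only main-phase trials count."""
    main = trials[trials["phase"] == "main"] if "phase" in trials else trials
    bad = main[(main["item_a"] == main["item_b"])
               | ~main["item_a"].between(0, n_scenes - 1)
               | ~main["item_b"].between(0, n_scenes - 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} trials reference invalid or identical scenes")
    participants = sorted(main["participant_id"].unique())
    counts = np.zeros((len(participants), n_scenes), dtype=int)
    opps = np.zeros_like(counts)
    for row, pid in enumerate(participants):
        grp = main[main["participant_id"] == pid]
        np.add.at(opps[row], grp["item_a"].to_numpy(), 1)
        np.add.at(opps[row], grp["item_b"].to_numpy(), 1)
        np.add.at(counts[row], grp["choice"].to_numpy(), 1)
    return SelectionFrequencies(participants, counts, opps)


def exclude_outliers(freqs: SelectionFrequencies, factor: float = 1.5) -> ExclusionReport:
    """Flag observers whose judgments disagree with the group.

    Each participant's frequency vector is correlated (Pearson) with every
    other participant's; participants whose *mean* correlation falls below
    Q1 - factor*IQR of these means are excluded.  A zero-variance frequency
    vector makes the correlation undefined and is itself grounds for
    exclusion.
    """
    n = len(freqs.participants)
    if n < 4:
        raise ValueError("outlier exclusion needs at least 4 participants")
    P = freqs.proportions
    mean_r = np.full(n, np.nan)
    degenerate = P.std(axis=1) < 1e-12
    for i in range(n):
        if degenerate[i]:
            continue
        rs = [stats.pearsonr(P[i], P[j])[0]
              for j in range(n) if j != i and not degenerate[j]]
        if rs:
            mean_r[i] = float(np.mean(rs))
    finite = mean_r[np.isfinite(mean_r)]
    q1, q3 = np.percentile(finite, [25, 75])
    fence = q1 - factor * (q3 - q1)
    excluded = ~np.isfinite(mean_r) | (mean_r < fence)
    reasons = {
        freqs.participants[i]: ("degenerate" if degenerate[i] else "outlier")
        for i in range(n) if excluded[i]
    }
    return ExclusionReport(freqs.participants, mean_r, float(fence), excluded, reasons)


def pool_frequencies(freqs: SelectionFrequencies,
                     keep: np.ndarray | None = None) -> np.ndarray:
    """Trial-weighted pooled proportion chosen per scene over kept observers."""
    keep = np.ones(len(freqs.participants), bool) if keep is None else np.asarray(keep, bool)
    if not keep.any():
        raise ValueError("no participants left after exclusion")
    counts = freqs.counts[keep].sum(axis=0)
    opps = freqs.opportunities[keep].sum(axis=0)
    return counts / np.clip(opps, 1, None)


def correlate(metric: np.ndarray, proportions: np.ndarray) -> float:
    """Pearson correlation between a metric and pooled choice proportions."""
    metric = np.asarray(metric, float)
    proportions = np.asarray(proportions, float)
    if metric.size < 3:
        raise ValueError("need at least 3 scenes")
    if metric.std() == 0 or proportions.std() == 0:
        raise ValueError("zero-variance input to correlation")
    return float(stats.pearsonr(metric, proportions)[0])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the dependency
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)]
        raise ValueError(f"collinear predictors: {bad or names}")


def fit_glm(metrics: pd.DataFrame, chosen: np.ndarray, opportunities: np.ndarray,
            family: str = "binomial"):
    """GLM of per-scene selection behaviour on metric predictors.

    ``binomial`` (default) is a logit model on (chosen, opportunities -
    chosen); ``gaussian`` regresses the raw proportion with identity link.
    Returns the fitted statsmodels results object.
    """
    names = list(metrics.columns)
    X = sm.add_constant(np.asarray(metrics, float))
    _check_rank(X, ["const"] + names)
    chosen = np.asarray(chosen, float)
    opps = np.asarray(opportunities, float)
    if family == "binomial":
        y = np.column_stack([chosen, opps - chosen])
        model = sm.GLM(y, X, family=sm.families.Binomial())
    elif family == "gaussian":
        model = sm.GLM(chosen / opps, X, family=sm.families.Gaussian())
    else:
        raise ValueError(f"unknown family {family!r}")
    res = model.fit()
    res.model.exog_names[:] = ["const"] + names
    return res


def fit_zscored_combo(predictors: pd.DataFrame, proportions: np.ndarray):
    """Cue-combination OLS on z-scored predictors.

    Returns ``(weights, model_r)``: the per-cue weights (in z-units) and the
    Pearson correlation between fitted and observed proportions.
    """
    if len(predictors) < 4:
        raise ValueError("need at least 4 scenes")
    X = np.asarray(predictors, float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError(f"constant predictor column(s): "
                         f"{[c for c, s in zip(predictors.columns, sd) if s == 0]}")
    Z = (X - X.mean(axis=0)) / sd
    _check_rank(sm.add_constant(Z), ["const"] + list(predictors.columns))
    res = sm.OLS(np.asarray(proportions, float), sm.add_constant(Z)).fit()
    weights = dict(zip(predictors.columns, res.params[1:]))
    r = correlate(res.fittedvalues, proportions)
    return weights, float(r)
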