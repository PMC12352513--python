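"""Maximum-likelihood psychometric fitting for 2AFC roughness discrimination.

Model: the probability of judging the comparison surface glossier than the
standard is a cumulative normal on log roughness with a symmetric lapse,

    P(log a) = lapse + (1 - 2 lapse) * Phi(s * (pse - log a)),

so P falls through 0.5 at the point of subjective equality (pse) and s > 0
because lower roughness looks glossier.  The reported ``slope`` is s in
1/log-units; the derivative of P at the PSE is (1 - 2 lapse) * s * phi(0).

Fits are penalised-likelihood with lapse bounded in [0, 0.1] and three
deterministic starts.  Uncertainty comes from nonparametric bootstrap over
trials within comparison level; condition differences are judged by the
bootstrap distribution of slope differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "bootstrap_slope_ci",
    "compare_slopes",
    "SlopeComparison",
]

_LAPSE_MAX = 0.1


@dataclass
class PsychometricFit:
    """Fitted 2AFC psychometric function on log roughness."""

    pse: float
    slope: float
    lapse: float
    converged: bool
    n_trials: int
    log_likelihood: float
    message: str = ""
    slope_ci: tuple[float, float] | None = None
    slope_se: float | None = None
    bootstrap_slopes: np.ndarray | None = field(default=None, repr=False)

    def predict(self, log_alpha) -> np.ndarray:
        z = self.slope * (self.pse - np.asarray(log_alpha, float))
        return self.lapse + (1 - 2 * self.lapse) * norm.cdf(z)


def _level_table(trials: pd.DataFrame) -> pd.DataFrame:
    g = trials.groupby("comparison_alpha")["response"]
    tab = pd.DataFrame({"n": g.size(), "k": g.sum().astype(int)}).reset_index()
    tab["log_alpha"] = np.log(tab["comparison_alpha"])
    return tab


def _neg_log_likelihood(theta, log_a, k, n):
    pse, slope, lapse = theta
    p = lapse + (1 - 2 * lapse) * norm.cdf(slope * (pse - log_a))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    # mild ridge on slope keeps the optimum finite on separable data
    return -(k * np.log(p) + (n - k) * np.log(1 - p)).sum() + 1e-4 * slope**2


def _identifiable(tab: pd.DataFrame) -> tuple[bool, str]:
    if len(tab) < 2:
        return False, "fewer than 2 distinct comparison levels"
    prop = tab["k"] / tab["n"]
    if (prop >= 0.5).all() or (prop <= 0.5).all():
        return False, "responses do not bracket 0.5; PSE not identifiable"
    return True, ""


def fit_psychometric(trials: pd.DataFrame, lapse_free: bool = True,
                     warm_start=None) -> PsychometricFit:
    """ML fit of the lapse-bounded cumulative normal to 2AFC trials.

    ``trials`` needs columns ``comparison_alpha`` (> 0) and ``response``
    (True when the comparison was judged glossier).  Non-identifiable data
    (e.g. all responses on one side of 0.5) yield an explicit failed fit,
    never a silent estimate.
    """
    if (trials["comparison_alpha"] <= 0).any():
        raise ValueError("comparison_alpha must be > 0")
    tab = _level_table(trials)
    ok, why = _identifiable(tab)
    n_tr = int(tab["n"].sum())
    if not ok:
        return PsychometricFit(np.nan, np.nan, np.nan, False, n_tr, np.nan, why)

    log_a, k, n = tab["log_alpha"].to_numpy(), tab["k"].to_numpy(), tab["n"].to_numpy()
    best = _fit_counts(log_a, k, n, lapse_free, warm_start=warm_start)
    pse, slope, lapse = best.x
    return PsychometricFit(float(pse), float(slope), float(lapse),
                           bool(best.success), n_tr, float(-best.fun),
                           best.message if not best.success else "")


def _fit_counts(log_a, k, n, lapse_free: bool = True, warm_start=None):
    """Optimize the penalized likelihood on a level table; multi-start
    L-BFGS-B unless a single warm start is supplied (bootstrap refits)."""
    span = max(log_a.max() - log_a.min(), 1e-3)
    if warm_start is not None:
        starts = [warm_start]
    else:
        order = np.argsort(k / n)  # proportions ascending for the crude inverse
        pse0 = float(np.interp(0.5, (k / n)[order], log_a[order]))
        if not np.isfinite(pse0):
            pse0 = float(log_a.mean())
        starts = [
            (pse0, 2.0 / span, 0.01),
            (float(log_a.mean()), 1.0 / span, 0.01),
            (float(log_a.mean()), 8.0 / span, 0.0),
            (pse0, -2.0 / span, 0.01),  # reversed response coding
        ]
    # slope may come out negative when responses are coded the other way
    # round; the usual glossier-is-lower-roughness data yields slope > 0
    bounds = [(log_a.min() - span, log_a.max() + span),
              (-1e4, 1e4),
              (0.0, _LAPSE_MAX if lapse_free else 1e-12)]
    best = None
    for s0 in starts:
        res = minimize(_neg_log_likelihood, s0, args=(log_a, k, n),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def bootstrap_slope_ci(trials: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                       level: float = 0.95) -> PsychometricFit:
    """Percentile bootstrap CI and SE for the slope, resampling trials
    within each comparison level.  Returns the point fit augmented with
    ``slope_ci``, ``slope_se`` and the bootstrap slope draws."""
    fit = fit_psychometric(trials)
    if not fit.converged or not np.isfinite(fit.slope):
        raise ValueError(f"cannot bootstrap a failed fit: {fit.message}")
    rng = np.random.default_rng(seed)
    tab = _level_table(trials)
    slopes = np.empty(n_boot)
    log_a, n = tab["log_alpha"].to_numpy(), tab["n"].to_numpy()
    p_hat = np.clip(tab["k"] / tab["n"], 0, 1)
    warm = (fit.pse, fit.slope, fit.lapse)
    for b in range(n_boot):
        k_b = rng.binomial(n, p_hat)
        prop = k_b / n
        if (prop >= 0.5).all() or (prop <= 0.5).all():
            slopes[b] = np.nan
            continue
        res = _fit_counts(log_a, k_b, n, warm_start=warm)
        slopes[b] = res.x[1] if res.success else np.nan
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.percentile(slopes, [50 * (1 - level), 50 * (1 + level)])
    fit.slope_ci = (float(lo), float(hi))
    fit.slope_se = float(slopes.std(ddof=1))
    fit.bootstrap_slopes = slopes
    return fit


@dataclass
class SlopeComparison:
    difference: float
    ci: tuple[float, float]
    significant: bool


def compare_slopes(fit_a: PsychometricFit, fit_b: PsychometricFit,
                   level: float = 0.95) -> SlopeComparison:
    """Bootstrap test of slope_a - slope_b; significant if the percentile CI
    of the difference excludes 0.  Both fits must carry bootstrap draws."""
    for f in (fit_a, fit_b):
        if f.bootstrap_slopes is None:
            raise ValueError("compare_slopes needs bootstrap_slope_ci fits")
    m = min(len(fit_a.bootstrap_slopes), len(fit_b.bootstrap_slopes))
    diffs = fit_a.bootstrap_slopes[:m] - fit_b.bootstrap_slopes[:m]
    lo, hi = np.percentile(diffs, [50 * (1 - level), 50 * (1 + level)])
    return SlopeComparison(
        difference=float(fit_a.slope - fit_b.slope),
        ci=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
    )
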