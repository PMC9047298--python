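"""Per-pig one-sided Wilcoxon rank-sum tests with Benjamini-Yekutieli FDR.

Each animal is its own experiment: its pre-surgery squeals are compared
with its post-surgery squeals, parameter by parameter, with a one-sided
rank-sum test whose direction encodes the expected post-surgery change
(frequency parameters and duration down, flatness / flux / RMS intensity
up).  Within each animal the 14 raw p-values are corrected with the
Benjamini-Yekutieli step-up procedure, which controls the false
discovery rate at the chosen level under arbitrary dependence between
parameters — appropriate here because the parameters are computed from
the same spectra and are far from independent.  Animals are never pooled
or compared with each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from squealkit.features import PARAMETER_NAMES

__all__ = [
    "DEFAULT_HYPOTHESES",
    "ComparisonResult",
    "wilcoxon_one_sided",
    "by_fdr",
    "run_comparison",
    "results_to_frame",
    "PrePostComparison",
]

#: Expected post-surgery direction per parameter.  Frequency parameters
#: and duration are expected to drop (spectral energy condenses into low
#: frequencies); flatness, flux and RMS intensity are expected to rise as
#: squeals become noisier and less structured.  HNR is listed as
#: "decrease" with the same reasoning even though it is known to behave
#: counter-intuitively on aperiodic voices.  All entries may be
#: overridden by configuration.
DEFAULT_HYPOTHESES: dict[str, str] = {
    "PF": "decrease",
    "Q50": "decrease",
    "Q50_2": "decrease",
    "Q50_10": "decrease",
    "Q50_min": "decrease",
    "Q50W": "decrease",
    "Q25": "decrease",
    "Dur": "decrease",
    "Q50_n": "decrease",
    "SF": "increase",
    "SF_Q50": "increase",
    "Flux": "increase",
    "RMSI": "increase",
    "HNR": "decrease",
}

assert set(DEFAULT_HYPOTHESES) == set(PARAMETER_NAMES)


@dataclass(frozen=True)
class ComparisonResult:
    """One pig x parameter pre/post comparison."""

    pig_id: str
    parameter: str
    n_pre: int
    n_post: int
    direction: str
    p_raw: float
    p_adj: float
    significant: bool
    significance_tier: str  # "ns", "*" (p_adj<=0.05) or "***" (p_adj<=0.001)


def wilcoxon_one_sided(x_pre, y_post, direction: str) -> float:
    """One-sided Wilcoxon rank-sum p-value for a post-surgery shift.

    ``direction="decrease"`` tests H1: post values are stochastically
    smaller than pre values; ``"increase"`` tests the opposite.  The
    exact null distribution is enumerated when the combined sample size
    is at most 20 and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used.

    Degenerate data (every value identical in both groups) returns
    p = 1.0 with a warning.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    x_pre = np.asarray(x_pre, dtype=np.float64)
    y_post = np.asarray(y_post, dtype=np.float64)
    if x_pre.size == 0 or y_post.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x_pre, y_post])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    alternative = "less" if direction == "decrease" else "greater"
    res = sps.mannwhitneyu(y_post, x_pre, alternative=alternative, method=method)
    return float(res.pvalue)


def by_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR correction.

    With m hypotheses and harmonic sum c(m) = sum_{i=1..m} 1/i, the
    sorted p-value of rank i is compared against i * alpha / (m * c(m));
    the adjusted p-value is the step-up minimum of m * c(m) * p_(i) / i,
    capped at 1.  Valid under arbitrary dependence among the tests.

    Returns
    -------
    rejections : bool array, original order
    p_adj : float array, original order
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw_adj = m * c_m * ranked / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(raw_adj[::-1])[::-1])
    p_adj = np.empty_like(adj)
    p_adj[order] = adj
    return p_adj <= alpha, p_adj


def _tier(p_adj: float, alpha: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= alpha:
        return "*"
    return "ns"


def run_comparison(
    features: pd.DataFrame,
    hypotheses: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-pig one-sided tests for every parameter, BY-corrected within pig.

    Parameters
    ----------
    features : DataFrame
        One row per squeal with columns ``pig_id``, ``phase`` ("pre"/"post")
        and one column per hypothesis parameter.
    hypotheses : dict, optional
        parameter -> expected post-surgery direction; defaults to
        :data:`DEFAULT_HYPOTHESES`.
    alpha : float
        FDR level per pig (default 0.05).

    Returns
    -------
    list of :class:`ComparisonResult`, grouped by pig in sorted pig order.
    Pigs missing a phase are skipped with a warning.
    """
    hypotheses = dict(DEFAULT_HYPOTHESES if hypotheses is None else hypotheses)
    missing = [p for p in hypotheses if p not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks hypothesis columns: {missing}")
    results: list[ComparisonResult] = []
    for pig_id in sorted(features["pig_id"].unique()):
        block = features[features["pig_id"] == pig_id]
        pre = block[block["phase"] == "pre"]
        post = block[block["phase"] == "post"]
        if pre.empty or post.empty:
            warnings.warn(f"pig {pig_id!r} lacks a pre or post phase; skipped", stacklevel=2)
            continue
        params = list(hypotheses)
        p_raw = [
            wilcoxon_one_sided(
                pre[param].to_numpy(), post[param].to_numpy(), hypotheses[param]
            )
            for param in params
        ]
        rejected, p_adj = by_fdr(p_raw, alpha=alpha)
        for param, pr, pa, rej in zip(params, p_raw, p_adj, rejected):
            results.append(
                ComparisonResult(
                    pig_id=str(pig_id),
                    parameter=param,
                    n_pre=len(pre),
                    n_post=len(post),
                    direction=hypotheses[param],
                    p_raw=float(pr),
                    p_adj=float(pa),
                    significant=bool(rej),
                    significance_tier=_tier(float(pa), alpha),
                )
            )
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results (machine-readable significance table)."""
    return pd.DataFrame(
        {
            "pig_id": [r.pig_id for r in results],
            "parameter": [r.parameter for r in results],
            "n_pre": [r.n_pre for r in results],
            "n_post": [r.n_post for r in results],
            "direction": [r.direction for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [r.significant for r in results],
            "tier": [r.significance_tier for r in results],
        }
    )


class PrePostComparison(BaseEstimator):
    """Estimator running the per-pig pre/post analysis on a feature table.

    ``fit`` expects the feature table produced by
    :class:`~squealkit.features.SquealFeatureExtractor` augmented with
    ``pig_id`` and ``phase`` columns.  After fitting:

    ``results_``
        list of :class:`ComparisonResult`
    ``summary_``
        the same results as a DataFrame

    Parameters
    ----------
    hypotheses : dict or None
        parameter -> expected post-surgery direction ("decrease"/"increase");
        None uses :data:`DEFAULT_HYPOTHESES`.
    alpha : float
        Per-pig FDR level (default 0.05).
    """

    def __init__(self, hypotheses: dict[str, str] | None = None, alpha: float = 0.05):
        self.hypotheses = hypotheses
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        self.results_ = run_comparison(X, hypotheses=self.hypotheses, alpha=self.alpha)
        self.summary_ = results_to_frame(self.results_)
        return self

    def significant_parameters(self, pig_id: str) -> list[str]:
        """Parameters whose BY-adjusted p-value clears alpha for one pig."""
        if not hasattr(self, "results_"):
            raise AttributeError("fit must be called first")
        return [
            r.parameter for r in self.results_ if r.pig_id == str(pig_id) and r.significant
        ]
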