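"""Evaluation statistics: accuracy, AUROC, stratified bootstrap CIs and paired tests.

The conventions used throughout:

* AUROC follows the Mann-Whitney formulation with midrank (0.5) credit for
  tied score pairs.
* Bootstrap confidence intervals are percentile intervals from resampling
  within strata, preserving stratum sizes (the stratum of a case is normally
  its true class label, so class prevalence is preserved in every replicate).
* The binomial test against chance is one-sided ("greater") by default,
  since the question asked is whether a classifier beats random guessing.
* McNemar's exact test doubles the smaller binomial tail of the discordant
  pairs and caps at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "PairedComparison",
    "accuracy",
    "auroc_binary",
    "auroc_ovr",
    "stratified_bootstrap_ci",
    "binomial_vs_chance",
    "mcnemar_exact",
    "bonferroni",
    "compare_paired",
]


@dataclass(frozen=True)
class MetricReport:
    """Point estimate of a metric with a stratified-bootstrap percentile CI."""

    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    r: int = 10_000
    level: float = 0.95
    strata: str = "class"
    seed: int | None = None


@dataclass(frozen=True)
class PairedComparison:
    """Exact McNemar comparison of two classifiers on paired cases."""

    n_pairs: int
    b: int  # correct by A only
    c: int  # correct by B only
    p_raw: float
    p_adjusted: float
    m: int = 4


def accuracy(pred_labels: Sequence, true_labels: Sequence) -> float:
    """Fraction of exactly matching labels."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("accuracy of empty input is undefined")
    return float(np.mean(pred == true))


def auroc_binary(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve for binary labels.

    Computed as the Mann-Whitney U statistic normalised by the number of
    positive-negative pairs; tied scores receive 0.5 credit (midranks).
    Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auroc_ovr(prob_matrix: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """One-vs-rest AUROC per class from a (n, k) probability matrix.

    Class c is scored with column c against the indicator ``label == c``.
    Classes absent from ``labels`` get ``nan`` (undefined).
    """
    p = np.asarray(prob_matrix, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[0] != y.size:
        raise ValueError("prob_matrix must be (n_cases, n_classes) aligned with labels")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("probability rows must sum to 1")
    out = np.full(p.shape[1], np.nan)
    for c in range(p.shape[1]):
        ind = (y == c).astype(int)
        if 0 < ind.sum() < ind.size:
            out[c] = auroc_binary(p[:, c], ind)
    return out


def stratified_bootstrap_ci(
    metric_fn: Callable[..., float],
    data: Sequence[np.ndarray],
    strata_labels: Sequence,
    r: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    metric_name: str = "metric",
) -> MetricReport:
    """Percentile bootstrap CI resampling within strata.

    ``data`` is a sequence of aligned 1-D (or first-axis aligned) arrays;
    ``metric_fn(*resampled_arrays)`` must return a scalar. Each replicate
    resamples case indices with replacement independently within every
    stratum, preserving stratum sizes.
    """
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("data arrays must be aligned on the first axis")
    strata = np.asarray(strata_labels)
    if strata.shape[0] != n:
        raise ValueError("strata_labels must be aligned with data")
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    if not groups or any(g.size == 0 for g in groups):
        raise ValueError("every stratum must be non-empty")

    rng = np.random.default_rng(seed)
    estimate = float(metric_fn(*arrays))
    # Draw all replicate indices per stratum at once, then assemble.
    idx = np.empty((r, n), dtype=np.intp)
    start = 0
    for g in groups:
        idx[:, start : start + g.size] = rng.choice(g, size=(r, g.size), replace=True)
        start += g.size
    reps = np.empty(r)
    for i in range(r):
        reps[i] = metric_fn(*(a[idx[i]] for a in arrays))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return MetricReport(
        metric=metric_name,
        estimate=estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        r=r,
        level=level,
        seed=seed,
    )


def binomial_vs_chance(
    n_correct: int, n: int, p0: float, alternative: str = "greater"
) -> float:
    """Exact binomial test of an observed accuracy against chance level p0."""
    if not (0 <= n_correct <= n):
        raise ValueError("n_correct must lie in [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binomtest(n_correct, n, p0, alternative=alternative).pvalue)


def mcnemar_exact(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> float:
    """Exact two-sided McNemar p-value on paired correctness indicators.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2), where b
    and c count the discordant pairs. No discordant pairs -> p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired inputs must have equal length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)
    return float(min(1.0, p))


def bonferroni(p_values: Sequence[float], m: int = 4) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def compare_paired(
    correct_a: Sequence[bool], correct_b: Sequence[bool], m: int = 4
) -> PairedComparison:
    """Full paired comparison record (McNemar exact + Bonferroni)."""
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    p = mcnemar_exact(a, b_arr)
    return PairedComparison(
        n_pairs=int(a.size),
        b=int(np.sum(a & ~b_arr)),
        c=int(np.sum(~a & b_arr)),
        p_raw=p,
        p_adjusted=float(min(1.0, m * p)),
        m=m,
    )
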