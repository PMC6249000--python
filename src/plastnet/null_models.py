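"""Resampling null models for correlated difference scores.

Two bespoke procedures:

**Shared-timepoint simulation null.**  Acute (t3 - t0) and chronic
(t12 - t3) stage changes share the middle scan, which induces an artifactual
negative correlation between them (-0.5 in expectation for i.i.d.
equal-variance measurements).  The null distribution of the acute-predicts-
chronic regression t statistic is therefore simulated: each simulation draws
three independent pseudo-timepoint vectors of standard normals, forms the
two pseudo-change vectors, regresses chronic on acute across regions and
records the slope's t statistic.  An observed t is significant when it falls
in the top or bottom ``tail_alpha`` of the simulated values.

**Full-versus-subset beta-difference permutation test.**  To test whether
regression betas differ between the full dataset and a subset of subjects,
each region's dependent value is drawn at random (independently, probability
1/2) from either dataset, the stepwise regression is rerun in full, and the
beta differences from the full-data reference model are recorded.  The
observed subset-minus-full beta differences are compared two-tailed against
this permutation distribution.

Rank p-values use the +1 correction, p = 2*min(#{T<=t}+1, #{T>=t}+1)/(n+1)
capped at 1, so a finite simulation never yields p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plasticity import (PREDICTOR_NAMES, PredictorSet, StageChange,
                         stepwise_select, zscore_columns, _ols)


@dataclass
class NullDistribution:
    statistics: np.ndarray
    seed: int
    tail_alpha: float = 0.025

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)

    @property
    def n_sims(self) -> int:
        return len(self.statistics)


def shared_timepoint_null(n_regions: int = 78, n_sims: int = 1000,
                          seed: int = 0,
                          tail_alpha: float = 0.025) -> NullDistribution:
    """Simulated null of the acute->chronic regression t statistic under
    three independent pseudo-timepoints per region."""
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_sims, 3, n_regions))
    acute = draws[:, 1] - draws[:, 0]
    chronic = draws[:, 2] - draws[:, 1]
    # slope t in simple regression == correlation t: t = r sqrt((n-2)/(1-r^2))
    ac = acute - acute.mean(axis=1, keepdims=True)
    cc = chronic - chronic.mean(axis=1, keepdims=True)
    r = (ac * cc).sum(axis=1) / np.sqrt(
        (ac ** 2).sum(axis=1) * (cc ** 2).sum(axis=1))
    t = r * np.sqrt((n_regions - 2) / (1.0 - r ** 2))
    return NullDistribution(t, seed=seed, tail_alpha=tail_alpha)


def rank_pvalue(observed: float, statistics: np.ndarray) -> float:
    """Two-tailed +1-corrected rank p-value against simulated statistics."""
    stats = np.asarray(statistics, dtype=float)
    n = len(stats)
    lo = int(np.sum(stats <= observed)) + 1
    hi = int(np.sum(stats >= observed)) + 1
    return min(1.0, 2.0 * min(lo, hi) / (n + 1))


def null_pvalue(observed_t: float,
                null: NullDistribution) -> tuple[float, bool]:
    """Two-tailed rank p and tail-based significance of an observed t.

    ``significant`` is True when the observed value lies within the top or
    bottom ``tail_alpha`` of the simulated values.
    """
    if null.n_sims == 0:
        raise ValueError("empty null distribution")
    p = rank_pvalue(observed_t, null.statistics)
    lo_q, hi_q = np.quantile(null.statistics,
                             [null.tail_alpha, 1.0 - null.tail_alpha])
    significant = bool(observed_t < lo_q or observed_t > hi_q)
    return p, significant


def _stepwise_betas(Xz: np.ndarray, y: np.ndarray, p_enter: float,
                    p_remove: float) -> np.ndarray:
    """Betas for all candidates (0 when unselected) after a full stepwise
    selection on pre-scaled columns."""
    included = stepwise_select(Xz, y, p_enter, p_remove)
    betas = np.zeros(Xz.shape[1])
    if included:
        beta_f, *_ = _ols(Xz[:, included], y)
        betas[included] = beta_f[1:]
    return betas


def beta_difference_test(dv_full: StageChange, dv_subset: StageChange,
                         predictors: PredictorSet, n_perm: int = 10000,
                         seed: int = 0, p_enter: float = 0.05,
                         p_remove: float = 0.10) -> dict[str, float]:
    """Permutation test for full-vs-subset differences in stepwise betas.

    Returns a two-tailed p-value per candidate predictor.  Stepwise
    selection is rerun in full for every permutation; predictors not
    selected in a given fit contribute beta 0.
    """
    dv_full.delta.check_aligned(dv_subset.delta)
    y_full = dv_full.delta.values
    y_sub = dv_subset.delta.values
    if predictors.region_ids and dv_full.delta.region_ids and \
            predictors.region_ids != dv_full.delta.region_ids:
        raise ValueError("region mismatch between predictors and dv")
    Xz = zscore_columns(predictors.as_matrix())
    n = len(y_full)
    ref = _stepwise_betas(Xz, y_full, p_enter, p_remove)
    observed = _stepwise_betas(Xz, y_sub, p_enter, p_remove) - ref
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_perm, Xz.shape[1]))
    for b in range(n_perm):
        take_sub = rng.random(n) < 0.5
        y_mix = np.where(take_sub, y_sub, y_full)
        diffs[b] = _stepwise_betas(Xz, y_mix, p_enter, p_remove) - ref
    return {name: rank_pvalue(float(observed[j]), diffs[:, j])
            for j, name in enumerate(PREDICTOR_NAMES)}
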