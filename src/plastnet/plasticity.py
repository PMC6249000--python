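"""Stage-change modelling: deltas, residualization and stepwise regression.

Plasticity is quantified as the change in a per-region metric between scan
timepoints: *acute* (pre-lesion to 3 months) and *chronic* (3 to 12 months).
Because both windows share the middle scan, chronic changes are residualized
on acute changes (ordinary least squares with intercept) before modelling;
the residuals are the chronic changes independent of the acute stage.

Each stage-change map is then regressed on four per-region predictors --
neuron density, non-neuronal cell density, hubness and pre-lesion
connectivity with the lesioned structure -- using forward-backward stepwise
selection with p-value entry/removal thresholds (defaults 0.05 / 0.10, the
canonical stepwise defaults).  Predictors are z-scored before selection so
betas are comparable across predictors; the dependent variable is left on
its own scale.  For predictors not retained in the final model, t and p are
reported as add-one-candidate partial statistics relative to the final
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .atlas import RegionVector

STAGES = ("acute", "chronic", "chronic_residual")
METRICS = ("participation", "within_module_fc", "grey_matter_logjac")

PREDICTOR_NAMES = ("neuron_density", "nonneuronal_density", "hubness",
                   "seed_fc")


@dataclass
class PredictorSet:
    """The four per-region predictors of plasticity, atlas-ordered."""

    neuron_density: RegionVector
    nonneuronal_density: RegionVector
    hubness: RegionVector
    seed_fc: RegionVector

    def __post_init__(self) -> None:
        base = self.neuron_density
        for name in PREDICTOR_NAMES[1:]:
            base.check_aligned(getattr(self, name))

    @property
    def region_ids(self) -> list[str]:
        return self.neuron_density.region_ids

    def as_matrix(self) -> np.ndarray:
        """n_regions x 4 matrix in canonical predictor order."""
        return np.column_stack([getattr(self, n).values
                                for n in PREDICTOR_NAMES])


@dataclass
class StageChange:
    """Per-region metric difference (later - earlier) for one stage."""

    delta: RegionVector
    stage: str
    metric: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; one of {STAGES}")
        if self.metric not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; one of {METRICS}")


@dataclass
class RegressionResult:
    """Final stepwise model for one stage-change map.

    ``betas`` are on the z-scored predictor scale; unselected predictors
    carry beta exactly 0.  ``t_stats``/``p_values`` hold final-model
    statistics for selected predictors and add-one partial statistics for
    the others.  With an empty final model F is NaN and r2 is 0.
    """

    selected: list[str]
    betas: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    F: float
    df: tuple[int, int]
    p_model: float
    r2: float
    n: int
    intercept: float = 0.0
    names: tuple[str, ...] = field(default=PREDICTOR_NAMES)


def stage_change(metric_later: RegionVector, metric_earlier: RegionVector,
                 stage: str, metric: str) -> StageChange:
    """Elementwise later - earlier metric difference."""
    metric_later.check_aligned(metric_earlier)
    delta = RegionVector(metric_later.values - metric_earlier.values,
                         metric_later.region_ids)
    return StageChange(delta, stage, metric)


def residualize_chronic(chronic: StageChange,
                        acute: StageChange) -> StageChange:
    """Chronic changes independent of acute changes: residuals of an OLS fit
    of chronic on acute (with intercept)."""
    chronic.delta.check_aligned(acute.delta)
    x = acute.delta.values
    y = chronic.delta.values
    if np.ptp(x) == 0:
        raise ValueError("acute change vector is constant")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return StageChange(RegionVector(resid, chronic.delta.region_ids),
                       "chronic_residual", chronic.metric)


def _tail2(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Two-tailed p from a t statistic (vectorized, via stdtr)."""
    return 2.0 * special.stdtr(df, -np.abs(t))


def _ols(Xc: np.ndarray, y: np.ndarray):
    """OLS with intercept prepended; returns beta, t, p, F, df, p_model, r2.

    ``Xc`` holds the (already scaled) predictor columns only.
    """
    n, k = Xc.shape
    X = np.column_stack([np.ones(n), Xc]) if k else np.ones((n, 1))
    XtX = X.T @ X
    Xty = X.T @ y
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    dfe = n - k - 1
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    mse = sse / dfe
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = _tail2(t, dfe)
    if k and sst > 0:
        r2 = 1.0 - sse / sst
        F = ((sst - sse) / k) / mse
        p_model = float(special.fdtrc(k, dfe, F))
    else:
        r2, F, p_model = 0.0, np.nan, 1.0
    return beta, t, p, F, (k, dfe), p_model, r2, sse


def zscore_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    return (X - X.mean(axis=0)) / sd


def _check_collinearity(Xz: np.ndarray, names) -> None:
    n, k = Xz.shape
    u, s, vt = np.linalg.svd(Xz, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        null = vt[-1]
        involved = [names[j] for j in range(k) if abs(null[j]) > 1e-8]
        raise ValueError(f"perfectly collinear predictors: {involved}")


def stepwise_select(Xz: np.ndarray, y: np.ndarray, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> list[int]:
    """Forward-backward stepwise selection on pre-scaled columns.

    Starting from the intercept-only model: add the candidate with the
    smallest partial-F p-value if it is below ``p_enter``; then drop any
    included predictor whose final-model p exceeds ``p_remove``; iterate to
    a fixed point.  Ties are broken by candidate column order.  Returns the
    selected column indices in entry order.
    """
    n, k = Xz.shape
    sst = float(((y - y.mean()) ** 2).sum())
    included: list[int] = []
    for _ in range(4 * k + 4):
        changed = False
        # forward; skipped once the fit is numerically perfect (partial
        # statistics on zero residuals are meaningless)
        *_, sse_cur = _ols(Xz[:, included], y)
        best_j, best_p = -1, np.inf
        if sse_cur > 1e-12 * max(sst, 1e-300):
            for j in range(k):
                if j in included:
                    continue
                _, t, p, *_ = _ols(Xz[:, included + [j]], y)
                pj = float(p[-1])
                if pj < best_p - 1e-15:
                    best_j, best_p = j, pj
        if best_j >= 0 and best_p < p_enter:
            included.append(best_j)
            changed = True
        # backward
        while included:
            _, t, p, *_ = _ols(Xz[:, included], y)
            pin = np.asarray(p[1:], dtype=float)  # skip intercept
            worst = int(np.argmax(pin))
            if pin[worst] > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return included


def stepwise_regression(predictors: PredictorSet | np.ndarray,
                        dv: StageChange | RegionVector | np.ndarray,
                        p_enter: float = 0.05,
                        p_remove: float = 0.10,
                        names=PREDICTOR_NAMES) -> RegressionResult:
    """Stepwise regression of a stage-change map on the candidate
    predictors (z-scored), with full reporting.

    Accepts either the domain containers or bare arrays (n x k predictor
    matrix and length-n dependent vector).
    """
    if isinstance(predictors, PredictorSet):
        X = predictors.as_matrix()
        names = PREDICTOR_NAMES
    else:
        X = np.asarray(predictors, dtype=float)
    if isinstance(dv, StageChange):
        y = dv.delta.values
    elif isinstance(dv, RegionVector):
        y = dv.values
    else:
        y = np.asarray(dv, dtype=float)
    n, k = X.shape
    if not (p_enter <= p_remove):
        raise ValueError("p_enter must be <= p_remove")
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} observations, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in predictors or dependent variable")
    Xz = zscore_columns(X)
    _check_collinearity(Xz, names)
    included = stepwise_select(Xz, y, p_enter, p_remove)

    beta_f, t_f, p_f, F, df, p_model, r2, _ = _ols(Xz[:, included], y)
    betas = {nm: 0.0 for nm in names}
    t_stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for pos, j in enumerate(included):
        betas[names[j]] = float(beta_f[pos + 1])
        t_stats[names[j]] = float(t_f[pos + 1])
        p_values[names[j]] = float(p_f[pos + 1])
    for j in range(k):
        if j in included:
            continue
        _, t_a, p_a, *_ = _ols(Xz[:, included + [j]], y)
        t_stats[names[j]] = float(t_a[-1])
        p_values[names[j]] = float(p_a[-1])
    return RegressionResult(
        selected=[names[j] for j in included],
        betas=betas, t_stats=t_stats, p_values=p_values,
        F=F, df=df, p_model=p_model, r2=float(r2), n=n,
        intercept=float(beta_f[0]), names=tuple(names))


def module_dispersion_anova(change: StageChange, partition) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of per-region stage change grouped by module.

    Regions with a missing change value are dropped; every module must
    retain at least 2 members and at least 2 modules must remain.
    """
    labels = np.asarray(partition.labels)
    vals = change.delta.values
    if len(labels) != len(vals):
        raise ValueError("partition does not cover the change vector")
    keep = ~np.isnan(vals)
    labels, vals = labels[keep], vals[keep]
    groups = [vals[labels == m] for m in np.unique(labels)]
    small = [int(m) for m, g in zip(np.unique(labels), groups) if len(g) < 2]
    if small:
        raise ValueError(f"modules with fewer than 2 members: {small}")
    if len(groups) < 2:
        raise ValueError("need at least 2 modules")
    F, p = stats.f_oneway(*groups)
    df = (len(groups) - 1, len(vals) - len(groups))
    return float(F), df, float(p)


def average_donor_densities(crosswalk: pd.DataFrame,
                            donor_densities: dict[str, float],
                            target_ids: list[str]) -> RegionVector:
    """Map donor-parcellation densities onto atlas regions.

    ``crosswalk`` has columns ``target`` (atlas region id) and ``donor``
    (area name in the donor study).  Where several donor areas map to one
    atlas region, their densities are averaged with equal weight.  Targets
    with no donor entry get NaN.
    """
    if not {"target", "donor"} <= set(crosswalk.columns):
        raise ValueError("crosswalk needs 'target' and 'donor' columns")
    out = np.full(len(target_ids), np.nan)
    grouped = crosswalk.groupby("target")["donor"].apply(list)
    for i, tid in enumerate(target_ids):
        donors = grouped.get(tid)
        if donors:
            out[i] = float(np.mean([donor_densities[d] for d in donors]))
    return RegionVector(out, list(target_ids))
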