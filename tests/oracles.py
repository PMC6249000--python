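"""Independent brute-force oracles used by the test suite.

Everything here is computed by naive enumeration or direct double-sum
formulas, deliberately sharing no code with the package implementation.
"""

import numpy as np


def set_partitions(n):
    """All set partitions of n elements as 0-based label arrays."""
    def rec(i, labels, maxl):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxl + 1):
            labels[i] = lab
            yield from rec(i + 1, labels, max(maxl, lab + 1))
    yield from rec(0, np.zeros(n, int), 0)


def brute_modularity(W, labels, gamma=1.0):
    """Direct double-sum Newman-Girvan Q on the positive part of W
    (diagonal zeroed, null term over all ordered pairs)."""
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, None)
    v = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    n = len(W)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * k[i] * k[j] / v
    return q / v


def brute_participation(W, labels):
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, None)
    n = len(W)
    out = np.zeros(n)
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            out[i] = 0.0
            continue
        acc = 0.0
        for s in np.unique(labels):
            acc += (W[i][labels == s].sum() / k) ** 2
        out[i] = 1.0 - acc
    return out


def brute_within_module(W, labels):
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    n = len(W)
    out = np.full(n, np.nan)
    for i in range(n):
        peers = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if peers:
            out[i] = np.mean([W[i, j] for j in peers])
    return out


def anova_oneway(groups):
    """Textbook one-way ANOVA from sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    F = (ssb / df1) / (ssw / df2)
    from scipy.stats import f
    return F, (df1, df2), float(f.sf(F, df1, df2))


def simple_ols_residuals(x, y):
    """Closed-form simple-regression residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    a = y.mean() - b * x.mean()
    return y - (a + b * x)


def stepwise_path_statsmodels(X, y, p_enter=0.05, p_remove=0.10):
    """Forward-backward stepwise selection replayed with statsmodels OLS
    fits at every decision point; returns selected column indices."""
    import statsmodels.api as sm
    n, k = X.shape
    included = []
    for _ in range(4 * k + 4):
        changed = False
        pvals = {}
        for j in range(k):
            if j in included:
                continue
            Xj = sm.add_constant(X[:, included + [j]])
            fit = sm.OLS(y, Xj).fit()
            pvals[j] = fit.pvalues[-1]
        if pvals:
            j_best = min(sorted(pvals), key=lambda j: pvals[j])
            if pvals[j_best] < p_enter:
                included.append(j_best)
                changed = True
        while included:
            fit = sm.OLS(y, sm.add_constant(X[:, included])).fit()
            pin = fit.pvalues[1:]
            worst = int(np.argmax(pin))
            if pin[worst] > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return included
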