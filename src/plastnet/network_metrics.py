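"""Community detection, consensus partitioning and per-node graph metrics.

The brain's modules are detected with the Louvain algorithm, maximizing
Newman-Girvan modularity with a resolution parameter ``gamma`` on the
positive part of the signed correlation matrix (higher gamma favours smaller
modules).  Because Louvain is stochastic, a stable "consensus" partition is
extracted from many seeded restarts by iteratively re-clustering the
region-by-region co-assignment frequency matrix until it becomes
block-binary.

Per-node metrics:

node strength
    k_i = sum of a region's connection weights (signed by default).
participation coefficient
    P_i = 1 - sum_s (kappa_is / k_i)^2 over modules s, on positive weights;
    0 for fully provincial regions, approaching 1 - 1/n_modules for regions
    whose positive weight is spread evenly over all modules.
within-module connectivity
    mean signed correlation with same-module regions (NaN for singletons).
hubness
    each region's score on the first principal component of the z-scored
    (strength, participation) matrix, signed so that hubness correlates
    positively with strength.

The Louvain implementation is deterministic given its seed: candidate nodes
are visited in seeded-random order and among equal-gain moves the
lowest-index community wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ConnectivityMatrix, RegionVector

_GAIN_TOL = 1e-12


@dataclass
class ModulePartition:
    """Region -> module labelling at a given resolution, with modularity Q."""

    labels: np.ndarray  # 1-based, contiguous
    gamma: float = 1.0
    Q: float = np.nan
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            # renumber to contiguous 1..n_modules preserving label order
            remap = {old: new for new, old in enumerate(uniq, start=1)}
            self.labels = np.array([remap[v] for v in self.labels])

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def onehot(self) -> np.ndarray:
        """n_regions x n_modules indicator matrix."""
        H = np.zeros((len(self.labels), self.n_modules))
        H[np.arange(len(self.labels)), self.labels - 1] = 1.0
        return H


def save_partition(partition: ModulePartition, path) -> None:
    ids = partition.region_ids or [str(i) for i in range(len(partition.labels))]
    pd.DataFrame({"region": ids, "module_id": partition.labels}).to_csv(
        path, sep="\t", index=False)


def load_partition(path, gamma: float = 1.0) -> ModulePartition:
    df = pd.read_csv(path, sep="\t")
    return ModulePartition(df["module_id"].to_numpy(int), gamma=gamma,
                           region_ids=df["region"].astype(str).tolist())


def _signed_parts(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.clip(W, 0.0, None), np.clip(-W, 0.0, None)


def modularity_score(W: ConnectivityMatrix, partition: ModulePartition,
                     gamma: float = 1.0, signed: bool = False) -> float:
    """Newman-Girvan modularity of a partition at resolution gamma.

    Q = (1/v+) sum_ij [W+_ij - gamma k+_i k+_j / v+] delta(c_i, c_j) on the
    positive part (W diagonal zeroed, degree-product null over all pairs).
    With ``signed=True`` the asymmetric signed variant
    Q = Q+ - (v-/(v+ + v-)) Q- is returned instead.
    """
    if len(partition.labels) != W.n_regions:
        raise ValueError("partition does not cover the matrix regions")
    Wd = W.off_diagonal()
    Wp, Wn = _signed_parts(Wd)

    def _q(M: np.ndarray) -> float:
        v = M.sum()
        if v == 0:
            return 0.0
        k = M.sum(axis=1)
        H = partition.onehot()
        within_w = float(np.einsum("is,ij,js->", H, M, H))
        kH = k @ H  # per-module total degree
        null = float((kH ** 2).sum()) / v
        return (within_w - gamma * null) / v

    qp = _q(Wp)
    if not signed:
        if Wp.sum() == 0:
            raise ValueError("zero total positive weight")
        return qp
    vp, vn = Wp.sum(), Wn.sum()
    if vp + vn == 0:
        raise ValueError("zero total weight")
    qn = _q(Wn)
    return qp - (vn / (vp + vn)) * qn


def _one_level(Mp: np.ndarray, Mn: np.ndarray, gamma: float,
               rng: np.random.Generator, signed: bool,
               init: np.ndarray | None = None) -> np.ndarray:
    """Louvain local-moving phase on an aggregated (super)graph.

    Node strengths include self-loop weight (aggregated within-community
    weight); self-loops contribute identically to every candidate move and
    are excluded from the per-community link sums.  ``init`` seeds the
    starting assignment (defaults to all-singletons).
    """
    n = len(Mp)
    vp = Mp.sum()
    vn = Mn.sum()
    kp = Mp.sum(axis=1)
    kn = Mn.sum(axis=1)
    labels = np.arange(n) if init is None else np.asarray(init, int).copy()
    sig_p = np.zeros(n)
    np.add.at(sig_p, labels, kp)
    sig_n = np.zeros(n)
    np.add.at(sig_n, labels, kn)
    neg_scale = (vn / (vp + vn)) if (signed and (vp + vn) > 0) else 0.0
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            sig_p[a] -= kp[i]
            sig_n[a] -= kn[i]
            lp = np.zeros(n)
            np.add.at(lp, labels, Mp[i])
            lp[a] -= Mp[i, i]
            if vp > 0:
                g = (lp - gamma * kp[i] * sig_p / vp) / vp
            else:
                g = np.zeros(n)
            if neg_scale > 0 and vn > 0:
                ln = np.zeros(n)
                np.add.at(ln, labels, Mn[i])
                ln[a] -= Mn[i, i]
                g = g - neg_scale * (ln - gamma * kn[i] * sig_n / vn) / vn
            # candidate targets: communities occupied by some j != i, plus a
            occ = np.zeros(n, bool)
            occ[labels] = True
            occ[labels[i]] = True
            if np.count_nonzero(labels == a) == 1:
                occ[a] = True  # staying alone is always allowed
            gain = np.where(occ, g, -np.inf)
            best = int(np.argmax(gain))  # ties -> lowest community index
            if gain[best] > gain[a] + _GAIN_TOL:
                new = best
                improved = True
            else:
                new = a
            labels[i] = new
            sig_p[new] += kp[i]
            sig_n[new] += kn[i]
    return labels


def _partition_quality(Wp: np.ndarray, Wn: np.ndarray, labels: np.ndarray,
                       gamma: float, signed: bool) -> float:
    """Q (positive-part or asymmetric signed) for internal comparisons."""
    _, compact = np.unique(labels, return_inverse=True)
    H = np.zeros((len(labels), compact.max() + 1))
    H[np.arange(len(labels)), compact] = 1.0

    def _q(M):
        v = M.sum()
        if v == 0:
            return 0.0
        k = M.sum(axis=1)
        within = float(np.einsum("is,ij,js->", H, M, H))
        kH = k @ H
        return (within - gamma * float((kH ** 2).sum()) / v) / v

    qp = _q(Wp)
    if not signed:
        return qp
    vp, vn = Wp.sum(), Wn.sum()
    if vp + vn == 0:
        return 0.0
    return qp - (vn / (vp + vn)) * _q(Wn)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same grouping."""
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    pairs = set(zip(ca.tolist(), cb.tolist()))
    return len(pairs) == len(np.unique(ca)) == len(np.unique(cb))


def _aggregate(M: np.ndarray, labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    H = np.zeros((len(labels), len(uniq)))
    for new, old in enumerate(uniq):
        H[labels == old, new] = 1.0
    return H.T @ M @ H


def louvain_partition(W: ConnectivityMatrix, gamma: float = 1.0,
                      seed: int = 0, signed: bool = False) -> ModulePartition:
    """Greedy two-phase Louvain maximization of modularity at resolution
    gamma, deterministic for a given seed.

    Operates on the positive part of the (diagonal-zeroed) weights by
    default; ``signed=True`` optimizes the asymmetric signed quality
    Q+ - (v-/(v+ + v-)) Q-.
    """
    Wd = W.off_diagonal()
    Wp, Wn = _signed_parts(Wd)
    n = W.n_regions
    if Wp.sum() == 0 and (not signed or Wn.sum() == 0):
        warnings.warn("all-zero positive weights; returning a single module")
        part = ModulePartition(np.ones(n, int), gamma=gamma,
                               region_ids=list(W.region_ids))
        part.Q = 0.0
        return part
    rng = np.random.default_rng(seed)
    # Each call explores three starting assignments -- all-singletons plus a
    # random 2-way and 3-way split -- because greedy single-node moves from
    # singletons cannot always reach coarse optima on weak-structure graphs.
    # The best final Q wins; ties keep the earlier (singleton-start) result.
    best_labels, best_q = None, -np.inf
    inits = [np.arange(n),
             rng.integers(0, 2, size=n),
             rng.integers(0, 3, size=n)]
    for labels_global in inits:
        # alternate node-level moves on the original graph with
        # supernode-level merge phases on the aggregated graph, to a fixed
        # point.  The node-level pass doubles as refinement (a merge-only
        # hierarchy cannot split supernodes); every accepted move strictly
        # increases Q, so the loop terminates.
        for _ in range(200):
            refined = _one_level(Wp, Wn, gamma, rng, signed,
                                 init=labels_global)
            uniq, compact = np.unique(refined, return_inverse=True)
            Mp = _aggregate(Wp, compact)
            Mn = _aggregate(Wn, compact)
            merged = _one_level(Mp, Mn, gamma, rng, signed)
            labels_new = merged[compact]
            stable = _same_partition(labels_new, labels_global)
            labels_global = labels_new
            if stable:
                break
        q = _partition_quality(Wp, Wn, labels_global, gamma, signed)
        if q > best_q + _GAIN_TOL:
            best_labels, best_q = labels_global, q
    labels_global = best_labels
    # contiguous 1-based labels ordered by first appearance
    order = {}
    for v in labels_global:
        if v not in order:
            order[v] = len(order) + 1
    labels = np.array([order[v] for v in labels_global])
    part = ModulePartition(labels, gamma=gamma, region_ids=list(W.region_ids))
    part.Q = modularity_score(W, part, gamma, signed=signed)
    return part


def coassignment_matrix(partitions: list[ModulePartition]) -> np.ndarray:
    """Region x region frequency of co-assignment to the same module."""
    n = len(partitions[0].labels)
    D = np.zeros((n, n))
    for p in partitions:
        D += (p.labels[:, None] == p.labels[None, :]).astype(float)
    return D / len(partitions)


def consensus_partition(W: ConnectivityMatrix, gamma: float = 1.0,
                        n_reps: int = 100, seed: int = 0, tau: float = 0.5,
                        max_iter: int = 50,
                        signed: bool = False) -> ModulePartition:
    """Stable consensus modules over ``n_reps`` seeded Louvain restarts.

    Builds the co-assignment frequency matrix of the restarts, thresholds it
    at ``tau``, re-clusters it, and iterates until the co-assignment matrix
    is block-binary (every pair of regions either always or never together),
    then reports that stable partition with its modularity on ``W``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    def _runs(matrix: ConnectivityMatrix, g: float) -> list[ModulePartition]:
        seeds = rng.integers(0, 2 ** 31, size=n_reps)
        return [louvain_partition(matrix, g, int(s), signed=signed)
                for s in seeds]

    parts = _runs(W, gamma)
    D = coassignment_matrix(parts)
    for _ in range(max_iter):
        binary = np.all((D < 1e-12) | (np.abs(D - 1.0) < 1e-12))
        if binary:
            labels = _components_of(D)
            part = ModulePartition(labels, gamma=gamma,
                                   region_ids=list(W.region_ids))
            part.Q = modularity_score(W, part, gamma, signed=signed)
            return part
        Dt = np.where(D < tau, 0.0, D)
        np.fill_diagonal(Dt, 0.0)
        Dm = ConnectivityMatrix(Dt, list(W.region_ids),
                                diagonal_policy="zeroed")
        parts = _runs(Dm, 1.0)
        D = coassignment_matrix(parts)
    agree = D[np.triu_indices_from(D, k=1)]
    raise RuntimeError(
        "consensus did not converge in "
        f"{max_iter} iterations; co-assignment min={agree.min():.3f} "
        f"mean={agree.mean():.3f} max={agree.max():.3f}")


def _components_of(D: np.ndarray) -> np.ndarray:
    """Connected-component labels of a binary block matrix."""
    n = len(D)
    labels = np.zeros(n, int)
    cur = 0
    for i in range(n):
        if labels[i] == 0:
            cur += 1
            stack = [i]
            while stack:
                j = stack.pop()
                if labels[j]:
                    continue
                labels[j] = cur
                stack.extend(np.flatnonzero((D[j] > 0.5) & (labels == 0)))
    return labels


def node_strength(W: ConnectivityMatrix, mode: str = "signed") -> RegionVector:
    """k_i = sum_{j != i} W_ij (signed by default, "positive" optional)."""
    Wd = W.off_diagonal()
    if mode == "positive":
        Wd = np.clip(Wd, 0.0, None)
    elif mode != "signed":
        raise ValueError(f"unknown strength mode {mode!r}")
    return RegionVector(Wd.sum(axis=1), list(W.region_ids))


def participation_coefficient(W: ConnectivityMatrix,
                              partition: ModulePartition) -> RegionVector:
    """P_i = 1 - sum_s (kappa_is / k_i)^2 on positive weights; P_i = 0 for
    regions with zero positive strength."""
    if len(partition.labels) != W.n_regions:
        raise ValueError("partition does not cover the matrix regions")
    Wp = np.clip(W.off_diagonal(), 0.0, None)
    k = Wp.sum(axis=1)
    H = partition.onehot()
    kappa = Wp @ H  # region x module positive weight
    with np.errstate(divide="ignore", invalid="ignore"):
        P = 1.0 - ((kappa / k[:, None]) ** 2).sum(axis=1)
    P[k == 0] = 0.0
    return RegionVector(P, list(W.region_ids))


def within_module_connectivity(W: ConnectivityMatrix,
                               partition: ModulePartition) -> RegionVector:
    """Mean signed weight to same-module regions (self excluded); NaN for
    regions alone in their module."""
    if len(partition.labels) != W.n_regions:
        raise ValueError("partition does not cover the matrix regions")
    Wd = W.off_diagonal()
    same = partition.labels[:, None] == partition.labels[None, :]
    np.fill_diagonal(same, False)
    counts = same.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, (Wd * same).sum(axis=1) / counts, np.nan)
    return RegionVector(means, list(W.region_ids))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input column")
    return (x - x.mean()) / sd


def hubness_scores(strength: RegionVector,
                   participation: RegionVector) -> tuple[RegionVector, float]:
    """Hubness as PC1 of the z-scored (strength, participation) matrix.

    Returns the per-region PC1 scores (signed so hubness correlates
    positively with strength) and the percentage of variance PC1 explains.
    """
    strength.check_aligned(participation)
    Z = np.column_stack([_zscore(strength.values),
                         _zscore(participation.values)])
    C = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(C)  # ascending
    v1 = evecs[:, -1]
    scores = Z @ v1
    if np.dot(scores, Z[:, 0]) < 0:
        scores = -scores
    var_explained = float(100.0 * evals[-1] / evals.sum())
    return (RegionVector(scores, list(strength.region_ids)), var_explained)
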