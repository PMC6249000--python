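"""Functional-connectivity construction from region timecourses.

Functional connectivity (FC) between two regions is the Pearson correlation
of their signal timecourses.  Matrices are kept continuous and unthresholded
(signed weights in [-1, 1]); group-level matrices are plain elementwise
averages across subjects by default, with Fisher-z averaging available as an
option.  The connectivity profile of a bilateral seed structure (here
typically the hippocampus) is the mean of its left- and right-hemisphere
correlation rows, restricted to the in-network regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .atlas import ConnectivityMatrix, RegionAtlas, RegionVector


@dataclass
class TimecourseSet:
    """Region x time matrix of signal samples."""

    samples: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a region x time matrix")
        if self.samples.shape[0] != len(self.region_ids):
            raise ValueError("samples row count does not match region_ids")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]


def compute_fc_matrix(tc: TimecourseSet) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of region timecourses.

    Raises if fewer than 3 timepoints are available or any region's
    timecourse is constant (zero variance), naming the offending region.
    """
    if tc.n_timepoints < 3:
        raise ValueError(
            f"need at least 3 timepoints, got {tc.n_timepoints}")
    sd = tc.samples.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [tc.region_ids[i] for i in bad]
        raise ValueError(f"constant (zero-variance) timecourse for: {names}")
    W = np.corrcoef(tc.samples)
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(W, list(tc.region_ids))


def average_fc_matrices(matrices: list[ConnectivityMatrix],
                        method: str = "raw") -> ConnectivityMatrix:
    """Average FC matrices across subjects.

    method="raw" (default) is the elementwise mean of the correlation
    weights; method="fisher_z" averages atanh-transformed weights and maps
    the mean back through tanh (the diagonal, and any exact +/-1, are passed
    through unchanged).
    """
    if not matrices:
        raise ValueError("empty matrix list")
    ids = matrices[0].region_ids
    for m in matrices[1:]:
        if m.region_ids != ids:
            raise ValueError("region id mismatch across matrices")
    stack = np.stack([m.weights for m in matrices])
    if method == "raw":
        W = stack.mean(axis=0)
    elif method == "fisher_z":
        with np.errstate(divide="ignore"):
            Z = np.arctanh(np.clip(stack, -1.0, 1.0))
        W = np.tanh(Z.mean(axis=0))
        W[np.isnan(W)] = stack.mean(axis=0)[np.isnan(W)]
    else:
        raise ValueError(f"unknown averaging method {method!r}")
    return ConnectivityMatrix(W, list(ids))


def seed_connectivity_profile(fc_full: ConnectivityMatrix, atlas: RegionAtlas,
                              seed_abbrev: str = "HC") -> RegionVector:
    """Bilateral seed FC profile over the in-network regions.

    Takes the correlation row of the left and the right instance of
    ``seed_abbrev`` from a full (all-region) matrix, averages the two, and
    restricts the result to in-network regions (the seed itself and any other
    excluded structures are omitted).
    """
    seed_ids = [f"{seed_abbrev}_L", f"{seed_abbrev}_R"]
    try:
        rows = [fc_full.region_ids.index(s) for s in seed_ids]
    except ValueError:
        raise ValueError(f"seed {seed_abbrev!r} absent from matrix") from None
    profile_full = fc_full.weights[rows].mean(axis=0)
    net_ids = atlas.network_region_ids
    idx = [fc_full.region_ids.index(r) for r in net_ids]
    return RegionVector(profile_full[idx], net_ids)


def correlate_with_tracing(fc_profile: RegionVector,
                           tracing: RegionVector) -> tuple[float, float]:
    """Pearson r between an FC profile and tract-tracing weights, with the
    two-tailed p-value from the t-transform on n-2 degrees of freedom.

    Pairs where either value is missing (NaN) are dropped (pairwise
    deletion).
    """
    fc_profile.check_aligned(tracing)
    x = fc_profile.values
    y = tracing.values
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return r, p
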