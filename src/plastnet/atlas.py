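"""Region atlas and shared data containers.

The analyses in this package operate on a fixed, ordered catalogue of brain
regions (a "regional map" of macroscopic cortical and subcortical areas, one
entry per hemisphere).  Every matrix and vector downstream is indexed by this
catalogue, so region order is fixed here once and preserved everywhere.

Three containers define the shared data model:

``RegionAtlas``
    Ordered region catalogue with per-region network-inclusion flags.  The
    bundled default has 82 entries (41 areas x 2 hemispheres); hippocampus
    and amygdala are flagged out-of-network bilaterally, leaving 78 regions
    for graph analyses.
``ConnectivityMatrix``
    Square symmetric matrix of signed, unthresholded Pearson correlations
    between region timecourses.
``RegionVector``
    One scalar per region (cell density, connectivity weight, log-Jacobian
    volume change, metric change, ...), with NaN representing missing.

All file formats are tab-delimited UTF-8 text with a header row.  Region
identifiers on disk are ``<abbrev>_<L|R>`` (e.g. ``HC_L``).

The bundled atlas fixes a region order (alphabetical within hemisphere, left
block first).  This order is a convention of this package, chosen because the
source atlas does not publish one; any consistent order gives identical
results as long as all inputs share it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_HEMI_SUFFIX = {"left": "L", "right": "R"}

#: absolute tolerance used when enforcing matrix symmetry on load
SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class RegionEntry:
    abbrev: str
    name: str
    hemisphere: str  # "left" | "right"
    in_network: bool

    @property
    def region_id(self) -> str:
        return f"{self.abbrev}_{_HEMI_SUFFIX[self.hemisphere]}"


@dataclass
class RegionAtlas:
    """Ordered catalogue of regions; the index space of the whole pipeline."""

    entries: list[RegionEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.hemisphere not in _HEMI_SUFFIX:
                raise ValueError(f"unknown hemisphere label: {e.hemisphere!r}")
            key = (e.abbrev, e.hemisphere)
            if key in seen:
                raise ValueError(f"duplicate region entry: {key}")
            seen.add(key)

    @property
    def n_total(self) -> int:
        return len(self.entries)

    @property
    def n_network(self) -> int:
        return sum(e.in_network for e in self.entries)

    @property
    def region_ids(self) -> list[str]:
        return [e.region_id for e in self.entries]

    @property
    def network_region_ids(self) -> list[str]:
        return [e.region_id for e in self.entries if e.in_network]

    def entry(self, region_id: str) -> RegionEntry:
        for e in self.entries:
            if e.region_id == region_id:
                return e
        raise KeyError(region_id)

    def network_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries) if e.in_network])


def load_region_table(path) -> RegionAtlas:
    """Read a region table (TSV: abbrev, name, hemisphere, in_network)."""
    df = pd.read_csv(path, sep="\t", dtype={"abbrev": str, "name": str,
                                            "hemisphere": str})
    required = {"abbrev", "name", "hemisphere", "in_network"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    entries = [
        RegionEntry(r.abbrev, r.name, r.hemisphere, bool(r.in_network))
        for r in df.itertuples()
    ]
    return RegionAtlas(entries)


def save_region_table(atlas: RegionAtlas, path) -> None:
    df = pd.DataFrame(
        {
            "abbrev": [e.abbrev for e in atlas.entries],
            "name": [e.name for e in atlas.entries],
            "hemisphere": [e.hemisphere for e in atlas.entries],
            "in_network": [int(e.in_network) for e in atlas.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def default_atlas() -> RegionAtlas:
    """The bundled 82-region regional-map atlas (78 network regions)."""
    ref = importlib.resources.files("plastnet.data") / "regional_map.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_region_table(p)


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region matrix of signed correlation weights."""

    weights: np.ndarray
    region_ids: list[str]
    diagonal_policy: str = "unit"  # "unit" | "zeroed"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.weights.shape[0] != len(self.region_ids):
            raise ValueError(
                f"matrix dimension {self.weights.shape[0]} does not match "
                f"{len(self.region_ids)} region ids"
            )
        asym = np.max(np.abs(self.weights - self.weights.T), initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:g} exceeds {SYMMETRY_TOL:g}")
        # average out numerically-insignificant asymmetry
        self.weights = (self.weights + self.weights.T) / 2.0
        if self.diagonal_policy not in ("unit", "zeroed"):
            raise ValueError(f"unknown diagonal_policy {self.diagonal_policy!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def off_diagonal(self) -> np.ndarray:
        """Weights with the diagonal zeroed (the form graph metrics use)."""
        W = self.weights.copy()
        np.fill_diagonal(W, 0.0)
        return W

    def subset(self, region_ids: list[str]) -> "ConnectivityMatrix":
        idx = [self.region_ids.index(r) for r in region_ids]
        return ConnectivityMatrix(self.weights[np.ix_(idx, idx)],
                                  list(region_ids), self.diagonal_policy)


def load_connectivity_matrix(path, atlas_or_ids) -> ConnectivityMatrix:
    """Read a labelled square TSV matrix, checking labels against the atlas.

    The first column holds row labels and the header row the column labels;
    both must match the atlas's network-region order exactly (or, when a list
    of region ids is given, that list).
    """
    ids = (atlas_or_ids.network_region_ids
           if isinstance(atlas_or_ids, RegionAtlas) else list(atlas_or_ids))
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != ids or list(df.index) != ids:
        raise ValueError("matrix labels do not match expected region order")
    W = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("matrix contains non-numeric or non-finite cells")
    return ConnectivityMatrix(W, ids)


def save_connectivity_matrix(cm: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(cm.weights, index=cm.region_ids, columns=cm.region_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class RegionVector:
    """Per-region scalar values; NaN marks an explicitly missing value."""

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.region_ids and len(self.region_ids) != len(self.values):
            raise ValueError("values and region_ids length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def check_aligned(self, other: "RegionVector") -> None:
        if self.region_ids and other.region_ids and \
                self.region_ids != other.region_ids:
            raise ValueError("region id mismatch between vectors")
        if len(self) != len(other):
            raise ValueError("vector length mismatch")


def load_region_vector(path) -> RegionVector:
    """Read a two-column TSV ``region<TAB>value``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("region vector file must have exactly two columns")
    return RegionVector(df.iloc[:, 1].to_numpy(dtype=float),
                        df.iloc[:, 0].astype(str).tolist())


def save_region_vector(vec: RegionVector, path, value_name: str = "value") -> None:
    ids = vec.region_ids or [str(i) for i in range(len(vec))]
    pd.DataFrame({"region": ids, value_name: vec.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
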