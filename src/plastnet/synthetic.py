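"""Synthetic lesion-plasticity studies with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a 78-region, three-timepoint (pre-lesion / 3-month / 12-month),
multi-subject resting-state connectome study with

* a planted module structure (4 blocks by default) expressed through a
  latent factor model -- every region loads on its module factor and on one
  global factor, which guarantees a positive-semidefinite latent covariance;
* hub regions (top ``hub_fraction`` of the hubness gradient) with amplified
  global-factor loadings, giving them high strength and participation;
* four smooth per-region predictor gradients (neuron density, non-neuronal
  cell density, a hubness proxy, seed connectivity) drawn from a Gaussian
  process and mixed to a configurable correlation structure;
* stage-change effects that are linear in the predictors plus Gaussian
  noise, injected into the metric-generating parameters (factor loadings)
  for the connectivity metrics, and directly into the per-region
  log-Jacobian volume series (which is itself a direct regional scalar);
* a planted bilateral seed-region (hippocampal) connectivity profile.

In ``fast`` mode the per-subject matrices are the latent correlation
matrices plus symmetric subject-level jitter; in ``timecourse`` mode finite
timecourses are sampled from the latent covariance and correlated, adding
realistic sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .atlas import ConnectivityMatrix, RegionVector, default_atlas
from .network_metrics import ModulePartition
from .plasticity import METRICS, PREDICTOR_NAMES, PredictorSet

TIMEPOINTS = ("pre", "3mo", "12mo")
STAGE_OF = {"acute": ("pre", "3mo"), "chronic": ("3mo", "12mo")}

#: default predictor correlation structure: neuron density correlates
#: positively and non-neuronal density negatively with the hubness gradient
DEFAULT_PREDICTOR_CORR = np.array([
    #  neuron  nonneur  hubness  seed_fc
    [1.00, -0.20, 0.40, 0.10],
    [-0.20, 1.00, -0.30, 0.00],
    [0.40, -0.30, 1.00, 0.20],
    [0.10, 0.00, 0.20, 1.00],
])

#: planted standardized effects (dv units per predictor SD) per
#: (stage, metric); rows follow PREDICTOR_NAMES order.  Signs mirror the
#: study structure the generator emulates: an acute participation drop in
#: hubs and seed-connected regions, a chronic participation rise with
#: non-neuronal density, chronic within-module gains with seed connectivity
#: and losses with neuron density, and chronic volume loss with seed
#: connectivity.
DEFAULT_EFFECTS = {
    ("acute", "participation"): (0.0, 0.0, -0.5, -0.5),
    ("chronic", "participation"): (0.0, 0.5, -0.5, 0.0),
    ("acute", "within_module_fc"): (0.0, 0.0, -0.5, 0.0),
    ("chronic", "within_module_fc"): (-0.5, 0.0, 0.0, 0.5),
    ("acute", "grey_matter_logjac"): (0.0, 0.0, 0.0, 0.0),
    ("chronic", "grey_matter_logjac"): (0.0, 0.0, 0.0, -0.5),
}


@dataclass
class SyntheticConfig:
    n_regions: int = 78
    n_subjects: int = 5
    n_timepoints_ts: int = 988
    module_sizes: tuple[int, ...] = (20, 20, 19, 19)
    within_corr: float = 0.6
    between_corr: float = 0.1
    weight_noise_sd: float = 0.05
    hub_fraction: float = 0.15
    hub_multiplier: float = 1.5
    predictor_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_PREDICTOR_CORR.copy())
    predictor_smoothness: float = 0.08
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: dict = field(default_factory=lambda: {m: 0.5 for m in METRICS})
    #: scale of loading perturbation per unit of planted metric change
    loading_gain: float = 0.15
    mode: str = "fast"  # "fast" | "timecourse"
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_regions:
            raise ValueError("module sizes must sum to n_regions")
        if any(s < 0 for s in list(self.noise_sd.values())
               + [self.weight_noise_sd]):
            raise ValueError("noise sds must be >= 0")
        self.predictor_corr = np.asarray(self.predictor_corr, dtype=float)
        ev = np.linalg.eigvalsh(self.predictor_corr)
        if ev.min() <= 1e-10:
            raise ValueError("predictor correlation target is not "
                             "positive-definite")


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    region_ids: list[str]
    predictors: PredictorSet
    partition: ModulePartition          # planted modules
    hub_flags: np.ndarray               # planted hub indicator
    fc: dict                            # timepoint -> list of per-subject CMs
    fc_full_pre: list                   # per-subject pre-lesion full matrix
    full_ids: list[str]
    logjac: dict                        # timepoint -> RegionVector
    seed_profile: RegionVector          # planted seed connectivity
    planted_changes: dict               # (stage, metric) -> np.ndarray
    ground_truth: dict


def _smooth_gradients(n: int, k: int, length_scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """k independent standardized draws from a 1-D Gaussian process."""
    x = np.linspace(0.0, 1.0, n)
    K = np.exp(-((x[:, None] - x[None, :]) / length_scale) ** 2)
    K += 1e-8 * np.eye(n)
    L = np.linalg.cholesky(K)
    Z = L @ rng.standard_normal((n, k))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    return Z


def generate_predictors(config: SyntheticConfig,
                        rng: np.random.Generator | None = None,
                        region_ids: list[str] | None = None) -> PredictorSet:
    """Four smooth per-region gradients with the configured correlation
    structure; density columns shifted/scaled strictly positive."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if region_ids is None:
        region_ids = _region_ids(config.n_regions)
    Z = _smooth_gradients(config.n_regions, 4, config.predictor_smoothness,
                          rng)
    L = np.linalg.cholesky(config.predictor_corr)
    M = Z @ L.T  # columns follow PREDICTOR_NAMES order
    neuron = 100.0 + 20.0 * M[:, 0]
    nonneur = 60.0 + 12.0 * M[:, 1]
    for v in (neuron, nonneur):
        if v.min() <= 0:
            v += 1.0 - v.min()
    return PredictorSet(
        neuron_density=RegionVector(neuron, region_ids),
        nonneuronal_density=RegionVector(nonneur, region_ids),
        hubness=RegionVector(M[:, 2], region_ids),
        seed_fc=RegionVector(0.3 + 0.25 * M[:, 3], region_ids),
    )


def _region_ids(n: int) -> list[str]:
    atlas = default_atlas()
    if n == atlas.n_network:
        return atlas.network_region_ids
    return [f"R{i:03d}" for i in range(1, n + 1)]


def planted_block_matrix(module_sizes, within: float = 0.6,
                         between: float = 0.1, noise_sd: float = 0.05,
                         seed: int = 0,
                         region_ids: list[str] | None = None
                         ) -> tuple[ConnectivityMatrix, ModulePartition]:
    """Direct block-structured weight matrix with symmetric Gaussian jitter.

    Off-diagonal weights are ``within`` inside planted blocks and
    ``between`` elsewhere, plus N(0, noise_sd) symmetric noise, clipped to
    [-1, 1]; diagonal unit.
    """
    n = int(sum(module_sizes))
    labels = np.concatenate([np.full(s, m + 1, int)
                             for m, s in enumerate(module_sizes)])
    W = np.where(labels[:, None] == labels[None, :], within, between)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n)) * noise_sd
    noise = (noise + noise.T) / np.sqrt(2.0)
    W = np.clip(W + noise, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    ids = region_ids or _region_ids(n)
    return (ConnectivityMatrix(W, ids),
            ModulePartition(labels, region_ids=ids))


def _loadings(config: SyntheticConfig, labels: np.ndarray,
              hub_flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-region module-factor and global-factor loadings."""
    mod = np.full(config.n_regions,
                  np.sqrt(config.within_corr - config.between_corr))
    glob = np.full(config.n_regions, np.sqrt(config.between_corr))
    glob = np.where(hub_flags, glob * config.hub_multiplier, glob)
    return mod, glob


def _correlation_from_loadings(labels: np.ndarray, mod: np.ndarray,
                               glob: np.ndarray) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    C = glob[:, None] * glob[None, :] + \
        np.where(same, mod[:, None] * mod[None, :], 0.0)
    bad = np.abs(C) >= 1.0
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"effect sizes produce out-of-range correlation at regions "
            f"({i}, {j}): {C[i, j]:.3f}")
    np.fill_diagonal(C, 1.0)
    return C


def _emit_matrix(C: np.ndarray, config: SyntheticConfig, ids: list[str],
                 rng: np.random.Generator) -> ConnectivityMatrix:
    if config.mode == "timecourse":
        # sample finite timecourses from the latent covariance
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 0.0, None)
        L = evecs * np.sqrt(evals)
        ts = (L @ rng.standard_normal((len(C), config.n_timepoints_ts)))
        W = np.corrcoef(ts)
        np.fill_diagonal(W, 1.0)
        return ConnectivityMatrix(W, ids)
    noise = rng.standard_normal(C.shape) * config.weight_noise_sd
    noise = (noise + noise.T) / np.sqrt(2.0)
    W = np.clip(C + noise, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(W, ids)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete synthetic study with known ground truth."""
    rng = np.random.default_rng(config.seed)
    ids = _region_ids(config.n_regions)
    predictors = generate_predictors(config, rng, ids)
    Xz = predictors.as_matrix()
    Xz = (Xz - Xz.mean(axis=0)) / Xz.std(axis=0, ddof=1)

    labels = np.concatenate([np.full(s, m + 1, int)
                             for m, s in enumerate(config.module_sizes)])
    n_hubs = max(1, int(round(config.hub_fraction * config.n_regions)))
    hub_flags = np.zeros(config.n_regions, bool)
    hub_flags[np.argsort(predictors.hubness.values)[-n_hubs:]] = True
    partition = ModulePartition(labels, region_ids=ids)

    # planted per-region change fields, linear in predictors plus noise
    planted: dict[tuple[str, str], np.ndarray] = {}
    for (stage, metric), eff in config.effects.items():
        mu = Xz @ np.asarray(eff, dtype=float)
        planted[(stage, metric)] = mu + rng.standard_normal(
            config.n_regions) * config.noise_sd[metric]

    # factor loadings per timepoint; stage effects scale the global loading
    # (drives participation/strength) and the module loading (drives
    # within-module connectivity)
    mod0, glob0 = _loadings(config, labels, hub_flags)
    loadings = {"pre": (mod0, glob0)}
    for stage, (t_from, t_to) in STAGE_OF.items():
        mod_prev, glob_prev = loadings[t_from]
        d_part = planted.get((stage, "participation"),
                             np.zeros(config.n_regions))
        d_wfc = planted.get((stage, "within_module_fc"),
                            np.zeros(config.n_regions))
        glob = np.clip(glob_prev * (1.0 + config.loading_gain * d_part),
                       0.02, None)
        mod = np.clip(mod_prev * (1.0 + config.loading_gain * d_wfc),
                      0.02, None)
        # keep each region's total loading norm inside the unit ball so all
        # pairwise correlations stay in (-1, 1) (Cauchy-Schwarz)
        norm2 = mod ** 2 + glob ** 2
        scale = np.sqrt(np.minimum(1.0, 0.95 / norm2))
        loadings[t_to] = (mod * scale, glob * scale)

    fc: dict[str, list[ConnectivityMatrix]] = {}
    for tp in TIMEPOINTS:
        mod, glob = loadings[tp]
        C = _correlation_from_loadings(labels, mod, glob)
        fc[tp] = [_emit_matrix(C, config, ids, rng)
                  for _ in range(config.n_subjects)]

    # full pre-lesion matrices including the excluded seed structures
    seed_profile = RegionVector(
        np.clip(predictors.seed_fc.values, -0.95, 0.95), ids)
    full_ids, fc_full_pre = _attach_seed_regions(
        fc["pre"], seed_profile, config, rng)

    # regional volume (log-Jacobian) series with direct linear effects
    logjac: dict[str, RegionVector] = {}
    base = rng.standard_normal(config.n_regions) * 0.01
    logjac["pre"] = RegionVector(base, ids)
    prev = base
    for stage, (t_from, t_to) in STAGE_OF.items():
        delta = planted.get((stage, "grey_matter_logjac"),
                            np.zeros(config.n_regions))
        prev = prev + delta
        logjac[t_to] = RegionVector(prev, ids)

    ground_truth = {
        "partition": labels.tolist(),
        "hub_flags": hub_flags.astype(int).tolist(),
        "betas": {f"{s}:{m}": list(map(float, e))
                  for (s, m), e in config.effects.items()},
        "predictor_names": list(PREDICTOR_NAMES),
        "seed_profile": seed_profile.values.tolist(),
        "seed": config.seed,
        "module_sizes": list(config.module_sizes),
    }
    return SyntheticStudy(
        config=config, region_ids=ids, predictors=predictors,
        partition=partition, hub_flags=hub_flags, fc=fc,
        fc_full_pre=fc_full_pre, full_ids=full_ids, logjac=logjac,
        seed_profile=seed_profile, planted_changes=planted,
        ground_truth=ground_truth)


def _attach_seed_regions(pre_mats, seed_profile: RegionVector,
                         config: SyntheticConfig, rng: np.random.Generator):
    """Extend pre-lesion matrices with bilateral seed (HC) and a second
    excluded structure (Amyg), giving the seed rows the planted profile."""
    n = config.n_regions
    ids = list(pre_mats[0].region_ids)
    extra = ["HC_L", "HC_R", "Amyg_L", "Amyg_R"]
    if n == 78:
        atlas = default_atlas()
        full_ids = atlas.region_ids
        extra = [r for r in full_ids if r not in ids]
    else:
        full_ids = ids + extra
    out = []
    for cm in pre_mats:
        m = len(full_ids)
        W = np.zeros((m, m))
        idx = [full_ids.index(r) for r in ids]
        W[np.ix_(idx, idx)] = cm.weights
        for r in extra:
            j = full_ids.index(r)
            if r.startswith("HC"):
                row = seed_profile.values
            else:
                row = np.clip(0.2 + 0.1 * rng.standard_normal(n), -0.9, 0.9)
            W[j, idx] = row
            W[idx, j] = row
        ex_idx = [full_ids.index(r) for r in extra]
        for a in ex_idx:
            for b in ex_idx:
                W[a, b] = 0.5 if a != b else 1.0
        np.fill_diagonal(W, 1.0)
        out.append(ConnectivityMatrix(W, list(full_ids)))
    return list(full_ids), out


def ground_truth_report(study: SyntheticStudy) -> dict:
    """Machine-readable manifest of the planted structure and seeds."""
    return dict(study.ground_truth)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)


def load_manifest(path) -> dict:
    with open(path) as f:
        return json.load(f)
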