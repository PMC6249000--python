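"""Config-driven orchestration of the full plasticity analysis.

The pipeline sequences the method end to end: group-mean connectivity per
timepoint -> consensus modules on the pre-lesion matrix -> per-timepoint
node metrics (with modules held fixed at the pre-lesion consensus) -> stage
changes -> residualization of chronic on acute -> stepwise regressions per
(stage, metric) -> shared-timepoint nulls -> module-dispersion ANOVAs ->
optional full-vs-subset beta-difference test -> a resolution (gamma) sweep
for robustness.  It writes TSV tables, a deterministic JSON summary and a
run log recording every seed and the software versions used.

Modules are defined once, on the pre-lesion consensus, and applied across
timepoints; per-timepoint re-partitioning is reported only as a diagnostic
(the modularity trajectory).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atlas import (RegionVector, default_atlas, load_connectivity_matrix,
                    load_region_vector, save_connectivity_matrix,
                    save_region_vector)
from .connectivity import average_fc_matrices, seed_connectivity_profile
from .network_metrics import (consensus_partition, hubness_scores,
                              modularity_score, node_strength,
                              participation_coefficient, save_partition,
                              within_module_connectivity)
from .null_models import (beta_difference_test, null_pvalue,
                          shared_timepoint_null)
from .plasticity import (PredictorSet, StageChange, module_dispersion_anova,
                         residualize_chronic, stage_change,
                         stepwise_regression)
from .synthetic import (STAGE_OF, TIMEPOINTS, SyntheticConfig, generate_study)

log = logging.getLogger("plastnet")

_GAMMA_GRID = tuple(round(0.8 + 0.1 * i, 1) for i in range(7))  # 0.8 .. 1.4


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    gamma: float = 1.0
    gamma_grid: tuple[float, ...] = _GAMMA_GRID
    consensus_n_reps: int = 10000
    sweep_n_reps: int = 100
    p_enter: float = 0.05
    p_remove: float = 0.10
    null_n_sims: int = 1000
    seed_abbrev: str = "HC"
    synthetic: dict | None = None
    inputs: dict | None = None
    beta_difference: dict | None = None  # {"n_subset": int, "n_perm": int}

    _INPUT_FIELDS = ("fc_pre", "fc_3mo", "fc_12mo", "fc_full_pre",
                     "neuron_density", "nonneuronal_density",
                     "logjac_pre", "logjac_3mo", "logjac_12mo")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in
                            cls.__dataclass_fields__.values()}  # type: ignore
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "out_dir" not in d:
            raise ValueError("config missing required field: out_dir")
        cfg = cls(**d)
        if (cfg.synthetic is None) == (cfg.inputs is None):
            raise ValueError(
                "config must set exactly one of 'synthetic' or 'inputs'")
        if cfg.inputs is not None:
            for name in cls._INPUT_FIELDS:
                if name not in cfg.inputs:
                    raise ValueError(f"config missing input field: {name}")
            for name in cls._INPUT_FIELDS:
                if not Path(cfg.inputs[name]).exists():
                    raise ValueError(
                        f"input path does not exist: {name} = "
                        f"{cfg.inputs[name]}")
        if isinstance(cfg.gamma_grid, list):
            cfg.gamma_grid = tuple(cfg.gamma_grid)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """A small self-contained synthetic demonstration configuration."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed, consensus_n_reps=100, sweep_n_reps=25,
        synthetic={"n_subjects": 5, "mode": "fast", "seed": seed},
        beta_difference={"n_subset": 2, "n_perm": 200},
    )


def _result_to_dict(res) -> dict:
    return {
        "selected": res.selected,
        "betas": res.betas,
        "t": res.t_stats,
        "p": res.p_values,
        "F": _num(res.F),
        "df": list(res.df),
        "p_model": _num(res.p_model),
        "r2": _num(res.r2),
        "n": res.n,
    }


def _num(x):
    x = float(x)
    return None if np.isnan(x) else x


def _acute_chronic_t(acute: StageChange, chronic: StageChange) -> float:
    """t statistic of the acute slope in chronic ~ acute (with intercept)."""
    x = acute.delta.values
    y = chronic.delta.values
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
    n = len(x)
    return r * np.sqrt((n - 2) / (1.0 - r ** 2))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report and writes it to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "run.log")
    rng_seeds = _derive_seeds(config.seed)
    log.info("plastnet %s | numpy %s | root seed %d",
             __version__, np.__version__, config.seed)
    log.info("derived seeds: %s", rng_seeds)

    # ---- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", rng_seeds["synthetic"])
        study = generate_study(SyntheticConfig(**syn))
        mean_fc = {tp: average_fc_matrices(study.fc[tp])
                   for tp in TIMEPOINTS}
        fc_full_pre = average_fc_matrices(study.fc_full_pre)
        logjac = study.logjac
        neuron = study.predictors.neuron_density
        nonneur = study.predictors.nonneuronal_density
        region_ids = study.region_ids
    else:
        inp = config.inputs
        atlas = default_atlas()
        region_ids = atlas.network_region_ids
        mean_fc = {tp: load_connectivity_matrix(inp[f"fc_{_tp_key(tp)}"],
                                                atlas)
                   for tp in TIMEPOINTS}
        fc_full_pre = load_connectivity_matrix(inp["fc_full_pre"],
                                               atlas.region_ids)
        logjac = {tp: load_region_vector(inp[f"logjac_{_tp_key(tp)}"])
                  for tp in TIMEPOINTS}
        neuron = load_region_vector(inp["neuron_density"])
        nonneur = load_region_vector(inp["nonneuronal_density"])
        study = None

    # ---- pre-lesion modules and per-timepoint metrics ---------------------
    atlas = default_atlas()
    partition = consensus_partition(mean_fc["pre"], gamma=config.gamma,
                                    n_reps=config.consensus_n_reps,
                                    seed=rng_seeds["consensus"])
    save_partition(partition, out / "consensus_partition.tsv")
    log.info("pre-lesion consensus: %d modules, Q=%.4f",
             partition.n_modules, partition.Q)

    metrics = {}
    for tp in TIMEPOINTS:
        strength = node_strength(mean_fc[tp])
        particip = participation_coefficient(mean_fc[tp], partition)
        wfc = within_module_connectivity(mean_fc[tp], partition)
        metrics[tp] = {"strength": strength, "participation": particip,
                       "within_module_fc": wfc}
        for name, vec in metrics[tp].items():
            save_region_vector(vec, out / f"{name}_{_tp_key(tp)}.tsv", name)
        save_connectivity_matrix(mean_fc[tp], out / f"fc_{_tp_key(tp)}.tsv")

    hub, pc1_var = hubness_scores(metrics["pre"]["strength"],
                                  metrics["pre"]["participation"])
    seed_fc = seed_connectivity_profile(fc_full_pre, atlas,
                                        config.seed_abbrev) \
        if len(fc_full_pre.region_ids) == atlas.n_total else \
        RegionVector(np.zeros(len(region_ids)), list(region_ids))
    predictors = PredictorSet(neuron_density=neuron,
                              nonneuronal_density=nonneur,
                              hubness=hub, seed_fc=seed_fc)

    # ---- stage changes, residualization, stepwise models ------------------
    changes: dict[tuple[str, str], StageChange] = {}
    for metric in ("participation", "within_module_fc"):
        for stg, (t0, t1) in STAGE_OF.items():
            changes[(stg, metric)] = stage_change(
                metrics[t1][metric], metrics[t0][metric], stg, metric)
    for stg, (t0, t1) in STAGE_OF.items():
        changes[(stg, "grey_matter_logjac")] = stage_change(
            logjac[t1], logjac[t0], stg, "grey_matter_logjac")

    null = shared_timepoint_null(len(region_ids), config.null_n_sims,
                                 seed=rng_seeds["null"])
    regressions = {}
    nulls_report = {}
    for metric in ("participation", "within_module_fc",
                   "grey_matter_logjac"):
        acute = changes[("acute", metric)]
        chronic = changes[("chronic", metric)]
        mask = ~(np.isnan(acute.delta.values) |
                 np.isnan(chronic.delta.values))
        acute = StageChange(RegionVector(acute.delta.values[mask]),
                            "acute", metric)
        chronic = StageChange(RegionVector(chronic.delta.values[mask]),
                              "chronic", metric)
        Xmask = predictors.as_matrix()[mask]
        t_obs = _acute_chronic_t(acute, chronic)
        p_null, sig = null_pvalue(t_obs, null)
        nulls_report[metric] = {"observed_t": float(t_obs),
                                "p_shared_timepoint": p_null,
                                "significant": sig}
        resid = residualize_chronic(chronic, acute)
        regressions[f"acute:{metric}"] = _result_to_dict(
            stepwise_regression(Xmask, acute, config.p_enter,
                                config.p_remove))
        regressions[f"chronic:{metric}"] = _result_to_dict(
            stepwise_regression(Xmask, resid, config.p_enter,
                                config.p_remove))

    # ---- module dispersion and modularity trajectory ----------------------
    anova = {}
    for stg in ("acute", "chronic"):
        ch = changes[(stg, "within_module_fc")]
        try:
            F, df, p = module_dispersion_anova(ch, partition)
            anova[stg] = {"F": float(F), "df": list(df), "p": float(p)}
        except ValueError as e:
            anova[stg] = {"error": str(e)}

    modularity = {}
    for tp in TIMEPOINTS:
        own = consensus_partition(mean_fc[tp], gamma=config.gamma,
                                  n_reps=config.sweep_n_reps,
                                  seed=rng_seeds[f"tp_{tp}"])
        modularity[tp] = {
            "Q_own_partition": float(own.Q),
            "n_modules": own.n_modules,
            "Q_prelesion_modules": float(
                modularity_score(mean_fc[tp], partition, config.gamma)),
        }

    sweep = []
    for g in config.gamma_grid:
        part_g = consensus_partition(mean_fc["pre"], gamma=g,
                                     n_reps=config.sweep_n_reps,
                                     seed=rng_seeds["sweep"])
        row = {"gamma": g, "n_modules": part_g.n_modules,
               "Q": float(part_g.Q)}
        p_post = participation_coefficient(mean_fc["3mo"], part_g)
        p_pre = participation_coefficient(mean_fc["pre"], part_g)
        dv = stage_change(p_post, p_pre, "acute", "participation")
        res = stepwise_regression(predictors.as_matrix(), dv,
                                  config.p_enter, config.p_remove)
        row["acute_participation_selected"] = res.selected
        sweep.append(row)

    # ---- optional beta-difference test ------------------------------------
    beta_diff = None
    if config.beta_difference and study is not None:
        n_sub = int(config.beta_difference.get("n_subset", 2))
        n_perm = int(config.beta_difference.get("n_perm", 1000))
        sub_fc = {tp: average_fc_matrices(study.fc[tp][:n_sub])
                  for tp in TIMEPOINTS}
        sub_part = metrics  # modules fixed at pre-lesion consensus
        sub_p3 = participation_coefficient(sub_fc["3mo"], partition)
        sub_p0 = participation_coefficient(sub_fc["pre"], partition)
        dv_sub = stage_change(sub_p3, sub_p0, "acute", "participation")
        dv_full = changes[("acute", "participation")]
        beta_diff = beta_difference_test(
            dv_full, dv_sub, predictors, n_perm=n_perm,
            seed=rng_seeds["beta_diff"], p_enter=config.p_enter,
            p_remove=config.p_remove)
        del sub_part

    report = {
        "software": {"plastnet": __version__, "numpy": np.__version__},
        "seeds": rng_seeds,
        "gamma": config.gamma,
        "n_regions": len(region_ids),
        "consensus": {"n_modules": partition.n_modules,
                      "Q": float(partition.Q),
                      "n_reps": config.consensus_n_reps},
        "hubness_pc1_variance_explained": float(pc1_var),
        "regressions": regressions,
        "shared_timepoint_nulls": nulls_report,
        "module_dispersion_anova": anova,
        "modularity": modularity,
        "gamma_sweep": sweep,
        "beta_difference_p": beta_diff,
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)
    log.info("report written to %s", out / "report.json")
    return report


def _tp_key(tp: str) -> str:
    return tp


def _derive_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["synthetic", "consensus", "null", "sweep", "beta_diff",
             "tp_pre", "tp_3mo", "tp_12mo"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def _setup_log(path) -> None:
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        log.removeHandler(h)
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.addHandler(logging.StreamHandler())
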