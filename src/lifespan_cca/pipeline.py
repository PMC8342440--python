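"""End-to-end orchestration: synthetic or file-based cohort -> network
features -> preprocessing -> (optional grid search) -> repeated k-fold
CCA -> age inference -> rich club -> RSA, with all numeric tables written
to disk and a manifest recording config, seed and per-stage wall time.

Two model variants share the code path: the full model (M1) and the
age-deconfounded variant (M2, ``deconfound_age=True``), whose comparison
isolates the age-driven part of the brain-behavior association.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import netfeatures, prep, richclub, rsa as rsa_mod
from .cca import age_correlation, bootstrap_null_p, bootstrap_se, cca_permutation_null
from .crossval import fit_two_view, grid_search, repeated_kfold_cca
from .synthdata import (
    CohortSpec,
    SubjectFeatureTable,
    generate_cohort,
    generate_label_maps,
    read_feature_table,
)

__all__ = ["RunConfig", "run_pipeline", "compare_models"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (a CohortSpec) or ``input_dir`` (a
    directory in the on-disk cohort layout) must be set.
    """

    synthetic: CohortSpec | None = None
    input_dir: str | None = None
    deconfound_age: bool = False          # False: full model (M1); True: M2
    k: int = 5
    n_repeats: int = 100
    grid_range: tuple[int, int] | None = None
    grid_step: int = 1
    grid_repeats: int = 10
    n_comp_pair: tuple[int, int] = (5, 5)  # (behavior, network) when no grid
    n_boot: int = 2000
    n_perm_null: int = 100
    rc_fraction: float = richclub.DEFAULT_CORE_FRACTION
    chord_percentile: float = 75.0
    seed: int = 0
    outdir: str = "results/run"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("set exactly one of synthetic spec or input_dir")
        for name in ("k", "n_repeats", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _load_inputs(config: RunConfig):
    from .synthdata import read_connectomes

    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        node_map, domain_map = generate_label_maps(config.synthetic)
        return cohort.behavior, cohort.connectomes, cohort.confounds, cohort.ages, node_map, domain_map
    d = Path(config.input_dir)
    behavior = read_feature_table(d / "behavior.tsv", d / "behavior_domains.tsv")
    conf = read_feature_table(d / "confounds.tsv")
    conf = conf.values  # plain DataFrame of confounds
    ages = pd.read_csv(d / "ages.tsv", sep="\t")["age"].to_numpy()
    stack = read_connectomes(d / "connectomes", d / "voxel_counts.tsv")
    node_map = pd.read_csv(d / "node_modules.tsv", sep="\t", index_col=0).iloc[:, 0]
    domain_map = behavior.variable_domains
    return behavior, stack, conf, ages, node_map, domain_map


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write every numeric artifact under
    ``config.outdir``.  Returns a bundle dict with the in-memory results
    (also used by :func:`compare_models`)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage):
        timings[stage] = round(time.perf_counter() - t0, 3)

    behavior, stack, confounds, ages, node_map, domain_map = _load_inputs(config)
    subject_ids = list(behavior.values.index)
    tick("load")

    # --- network features ---------------------------------------------------
    nets = netfeatures.consensus_threshold(netfeatures.build_density_networks(stack))
    deg = netfeatures.degree_table(nets, subject_ids)
    network = SubjectFeatureTable(deg.astype(float), node_map.loc[deg.columns])
    _write_tsv(deg, out / "node_degree.tsv")
    np.savetxt(out / "edge_mask.txt", nets.edge_mask.astype(int), fmt="%d")
    summaries = pd.DataFrame(
        [netfeatures.graph_summaries(nets.densities[i]) for i in range(nets.n_subjects)],
        index=subject_ids,
    )
    _write_tsv(summaries, out / "graph_summaries.tsv")
    trends = []
    for col in ("highest_degree", "density", "efficiency"):
        fit = netfeatures.quadratic_trend(summaries[col].to_numpy(), ages)
        trends.append({"measure": col, "quadratic_term": fit.quadratic_term,
                       "r_squared": fit.r_squared, "aicc": fit.aicc, "n_points": fit.n_points})
    _write_tsv(pd.DataFrame(trends).set_index("measure"), out / "lifespan_trends.tsv")
    tick("netfeatures")

    # --- behavior filtering (once, on the full sample) ----------------------
    behavior_f, report = prep.filter_variables(behavior)
    _write_tsv(report.set_index("variable"), out / "removal_report.tsv")
    net_keep = [c for c in network.values.columns if network.values[c].std(ddof=1) > 0]
    network_f = SubjectFeatureTable(network.values[net_keep], network.variable_domains[net_keep])
    tick("filter")

    # --- component-pair selection -------------------------------------------
    if config.grid_range is not None:
        gs = grid_search(
            behavior_f, network_f, ages, confounds=confounds,
            p_range=config.grid_range, k=config.k, n_repeats=config.grid_repeats,
            seed=config.seed, step=config.grid_step, deconfound_age=config.deconfound_age,
        )
        _write_tsv(gs.grid.set_index(["p_brain", "p_behavior"]), out / "grid_search.tsv")
        pair = (gs.best_pair[1], gs.best_pair[0])  # (behavior, network)
        grid_info = {"best_pair_brain_behavior": list(gs.best_pair),
                     "n_cells": gs.n_cells, "n_models_total": gs.n_models_total}
    else:
        pair = config.n_comp_pair
        grid_info = None
    tick("grid")

    # --- repeated k-fold CCA -------------------------------------------------
    cv = repeated_kfold_cca(
        behavior_f, network_f, ages, confounds=confounds, k=config.k,
        n_repeats=config.n_repeats, n_comp_pair=pair, seed=config.seed,
        deconfound_age=config.deconfound_age,
    )
    fac = pd.DataFrame(
        np.column_stack([cv.holdout_F1[:, 0], cv.holdout_F2[:, 0]]),
        index=subject_ids, columns=["CA1_behavior", "CA1_network"],
    )
    _write_tsv(fac, out / "holdout_factors_CA1.tsv")
    L1 = pd.DataFrame(cv.holdout_L1, index=behavior_f.variable_ids)
    L2 = pd.DataFrame(cv.holdout_L2, index=network_f.variable_ids)
    _write_tsv(L1, out / "holdout_loadings_behavior.tsv")
    _write_tsv(L2, out / "holdout_loadings_network.tsv")
    tick("crossval")

    # --- age inference -------------------------------------------------------
    fit = age_correlation(cv.holdout_F1[:, 0], cv.holdout_F2[:, 0], ages)
    X = np.column_stack([cv.holdout_F1[:, 0], cv.holdout_F2[:, 0]])
    p = bootstrap_null_p(X, ages, n_boot=config.n_boot, seed=config.seed)
    bmean, bse = bootstrap_se(X, ages, n_boot=config.n_boot, seed=config.seed + 1)
    reference = fit_two_view(behavior_f, network_f, confounds, pair, age=ages,
                             deconfound_age=config.deconfound_age, orient_to=ages)
    null_rho = cca_permutation_null(
        reference.prep1["basis"].scores, reference.prep2["basis"].scores,
        n_perm=config.n_perm_null, seed=config.seed,
    )
    inference = {
        "rho1_holdout_median": float(cv.rho_median[0]),
        "rho1_holdout_se": float(cv.rho_se[0]),
        "rho_holdout_median": cv.rho_median.tolist(),
        "r_age": fit.r_age, "r_age_median_cv": cv.r_age_median, "r_age_se_cv": cv.r_age_se,
        "r_age_boot_p": p, "r_age_boot_mean": bmean, "r_age_boot_se": bse,
        "rho1_perm_null_q95": float(np.quantile(null_rho, 0.95)),
        "rho1_insample": float(reference.model.canonical_corrs[0]),
        "n_factors": int(cv.holdout_F1.shape[1]),
        "n_comp_pair_behavior_network": list(pair),
    }
    tick("inference")

    # --- rich club ------------------------------------------------------------
    mean_net = richclub.average_network(nets)
    part = richclub.rich_club_partition(mean_net, fraction=config.rc_fraction)
    pc = richclub.participation_coefficient(mean_net, part)
    # network CA1 loadings aligned to all nodes (filtered-out nodes -> NaN)
    l2_ca1 = pd.Series(cv.holdout_L2[:, 0], index=network_f.variable_ids).reindex(deg.columns)
    ok = l2_ca1.notna().to_numpy()
    sub_part = richclub.rich_club_partition(mean_net[np.ix_(ok, ok)], fraction=config.rc_fraction) \
        if (~ok).any() else part
    assoc = richclub.loading_degree_association(
        l2_ca1.to_numpy()[ok], sub_part, n_boot=min(config.n_boot, 2000), seed=config.seed
    )
    node_table = pd.DataFrame({
        "degree": part.degree, "norm_degree": part.norm_degree,
        "core": part.is_core.astype(int), "participation": pc,
        "ca1_loading": l2_ca1.to_numpy(),
    }, index=deg.columns)
    _write_tsv(node_table, out / "richclub_nodes.tsv")
    tick("richclub")

    # --- RSA -------------------------------------------------------------------
    network_modules = list(dict.fromkeys(node_map))
    behavior_domains = list(dict.fromkeys(domain_map))
    L_stacked = pd.concat([L2, L1])
    row_domains = pd.Series(
        ["network"] * len(L2) + ["behavior"] * len(L1), index=L_stacked.index
    )
    S = rsa_mod.loading_dissimilarity(L_stacked, row_domains)
    module_map = pd.concat([node_map, domain_map])
    module_order = [m for m in network_modules if (module_map.loc[L2.index] == m).any()] + \
                   [d for d in behavior_domains if (module_map.loc[L1.index] == d).any()]
    S_mod, S_sd = rsa_mod.module_average(S, module_map, module_order)
    _write_tsv(S.values, out / "rsa_full.tsv")
    _write_tsv(S_mod, out / "rsa_modules_mean.tsv")
    _write_tsv(S_sd, out / "rsa_modules_sd.tsv")
    net_mods = [m for m in module_order if m in network_modules]
    beh_mods = [m for m in module_order if m in behavior_domains]
    btn = S_mod.loc[net_mods, beh_mods]
    chord = rsa_mod.chord_data(btn, percentile=config.chord_percentile)
    pd.DataFrame(chord["edges"], columns=["network_module", "behavior_domain", "weight"]).to_csv(
        out / "chord_edges.tsv", sep="\t", index=False
    )
    summary_beh = rsa_mod.module_loading_summary(
        L1.iloc[:, 0], domain_map, ses=pd.Series(cv.holdout_L1_se[:, 0], index=L1.index)
    )
    summary_net = rsa_mod.module_loading_summary(
        L2.iloc[:, 0], node_map, ses=pd.Series(cv.holdout_L2_se[:, 0], index=L2.index)
    )
    _write_tsv(summary_beh.table, out / "module_loading_summary_behavior.tsv")
    _write_tsv(summary_net.table, out / "module_loading_summary_network.tsv")
    tick("rsa")

    with open(out / "inference.json", "w") as fh:
        json.dump(inference, fh, indent=1)

    manifest = {
        "config": {k: (asdict(v) if isinstance(v, CohortSpec) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "grid": grid_info,
        "timings_s": timings,
        "file_hashes": {f.name: _hash_file(f) for f in sorted(out.iterdir()) if f.is_file()
                        and f.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    return {
        "config": config, "inference": inference, "cv": cv,
        "S_modules": S_mod, "btn": btn, "chord": chord,
        "subject_ids": subject_ids, "module_order": module_order,
        "net_modules": net_mods, "beh_modules": beh_mods,
        "outdir": str(out),
    }


def compare_models(bundle_m1: dict, bundle_m2: dict) -> dict:
    """Compare the full model against the age-deconfounded variant.

    Tabulates first-axis correlation and age association for both, computes
    the module-level difference matrix S_d = S1 - S2 with its
    brain-to-behavior block and chord data, and flags whether the
    age-deconfounded model's rho1 falls inside its permutation null band.
    """
    if bundle_m1["subject_ids"] != bundle_m2["subject_ids"]:
        raise ValueError("cohort mismatch between bundles")
    i1, i2 = bundle_m1["inference"], bundle_m2["inference"]
    S_d = rsa_mod.rsa_difference(bundle_m1["S_modules"], bundle_m2["S_modules"])
    btn_d = S_d.loc[bundle_m1["net_modules"], bundle_m1["beh_modules"]]
    report = {
        "m1": {"rho1": i1["rho1_holdout_median"], "r_age": i1["r_age"], "p": i1["r_age_boot_p"]},
        "m2": {"rho1": i2["rho1_holdout_median"], "r_age": i2["r_age"], "p": i2["r_age_boot_p"]},
        "m2_rho1_within_null": bool(i2["rho1_holdout_median"] <= i2["rho1_perm_null_q95"]),
        "S_d": S_d,
        "btn_difference": btn_d,
    }
    try:
        # chord_data thresholds r = 1 - block, so feed 1 - |S_d| to rank
        # module pairs by the magnitude of the age-isolated change
        report["chord_d"] = rsa_mod.chord_data(1.0 - btn_d.abs())
    except ValueError:
        report["chord_d"] = None
    return report
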