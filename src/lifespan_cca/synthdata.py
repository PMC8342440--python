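"""Synthetic lifespan cohorts for exercising the brain-behavior association pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, without any imaging: subjects evenly sampled across the adult
lifespan, a latent "aging axis" shaped as an inverted U of age, behavioral
variables coupled to that axis with mixed signs, physiological confounds
mildly correlated with age, sparse missingness, injected extreme outliers,
and per-subject structural connectomes (streamline-count matrices) whose
expected degree follows the same latent axis.

Every generated quantity is recomputable from the ``truth`` record, so unit
and recovery tests can compare pipeline estimates against planted values.
All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, one child stream per component,
so adding one generator never perturbs another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "ConfoundTable",
    "SyntheticCohort",
    "generate_cohort",
    "generate_connectomes",
    "generate_label_maps",
    "planted_axis_cohort",
    "module_coupled_cohort",
    "write_cohort",
    "read_feature_table",
    "read_connectomes",
]

NODE_MODULES = (
    "visual",
    "somatomotor",
    "limbic",
    "ventral_attention",
    "dorsal_attention",
    "frontoparietal",
    "default_mode",
    "hippocampus",
    "amygdala",
    "subcortical",
)

BEHAVIOR_DOMAINS = (
    "attention",
    "memory",
    "language",
    "emotion",
    "motor",
    "social",
    "clinical",
)

CONFOUND_COLUMNS = ("sex", "height", "weight", "heart_rate", "systolic_bp", "diastolic_bp")

#: target |r| with age for each confound column; capped at 0.3 so that
#: deconfounding cannot silently remove the latent age signal itself.
_CONFOUND_AGE_R = {
    "sex": 0.0,
    "height": -0.10,
    "weight": 0.15,
    "heart_rate": 0.10,
    "systolic_bp": 0.30,
    "diastolic_bp": 0.25,
}

_CONFOUND_LOC_SCALE = {
    "height": (170.0, 10.0),
    "weight": (75.0, 12.0),
    "heart_rate": (68.0, 10.0),
    "systolic_bp": (125.0, 15.0),
    "diastolic_bp": (80.0, 10.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic lifespan cohort.

    Defaults mirror the study conditions the pipeline is meant to handle:
    594 subjects evenly sampled over ages 18-88 (seven decade bins), 388
    raw behavioral variables of which ~54 are expected to fail quality
    filters (leaving ~334), 376 connectome nodes, roughly half of the
    behavior couplings increasing with the latent axis and half decreasing.
    """

    n_subjects: int = 594
    age_range: tuple[float, float] = (18.0, 88.0)
    n_age_bins: int = 7
    n_behavior_vars: int = 388
    n_nodes: int = 376
    frac_increasing: float = 0.5
    latent_peak_age: float = 40.0
    coupling_mean: float = 0.6
    coupling_sd: float = 0.25
    noise_sd: float = 0.8
    missing_rate: float = 0.02
    n_dead_vars: int = 20
    n_outlier_cells: int = 34
    degree_coupling: float = 0.5
    rare_edge_frac: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.frac_increasing <= 1.0):
            raise ValueError("frac_increasing must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")
        for name in ("missing_rate", "rare_edge_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_behavior_vars < self.n_dead_vars:
            raise ValueError("n_behavior_vars must be >= n_dead_vars")
        if self.n_age_bins <= 0:
            raise ValueError("n_age_bins must be positive")
        if self.degree_coupling < 0:
            raise ValueError("degree_coupling must be >= 0")


@dataclass
class ConfoundTable:
    """Per-subject nuisance variables: sex, height, weight, heart rate, blood pressure."""

    values: pd.DataFrame  # one row per subject, columns = CONFOUND_COLUMNS

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("confound table must have no missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.values)


@dataclass
class SubjectFeatureTable:
    """Subjects x variables matrix with a missingness mask and domain labels.

    ``values`` holds NaN at missing cells; ``mask`` is True where observed.
    """

    values: pd.DataFrame
    variable_domains: pd.Series  # index = variable ids, values = domain label

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "SubjectFeatureTable":
        return SubjectFeatureTable(self.values.copy(), self.variable_domains.copy())


@dataclass
class ConnectomeStack:
    """Per-subject streamline-count matrices plus per-node voxel counts."""

    counts: np.ndarray  # (n_subjects, n_nodes, n_nodes) nonnegative ints
    voxel_counts: np.ndarray  # (n_nodes,) positive ints
    node_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(self.voxel_counts <= 0):
            raise ValueError("voxel counts must be positive")
        if not np.array_equal(self.counts, np.swapaxes(self.counts, 1, 2)):
            raise ValueError("streamline-count matrices must be symmetric")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SyntheticCohort:
    ages: np.ndarray
    latent: np.ndarray
    confounds: ConfoundTable
    behavior: SubjectFeatureTable
    connectomes: ConnectomeStack | None
    truth: dict = field(default_factory=dict)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _binned_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform ages within equal-width bins, equal counts per bin.

    The remainder (n mod bins) is assigned deterministically to the earliest
    bins so repeated calls with the same spec agree on bin sizes.
    """
    lo, hi = spec.age_range
    edges = np.linspace(lo, hi, spec.n_age_bins + 1)
    base, rem = divmod(spec.n_subjects, spec.n_age_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(spec.n_age_bins)]
    ages = np.concatenate(
        [rng.uniform(edges[b], edges[b + 1], size=sizes[b]) for b in range(spec.n_age_bins)]
    )
    return np.sort(ages)


def _truncnorm(rng: np.random.Generator, size, bound: float = 2.5) -> np.ndarray:
    """Standard normal truncated to +-bound; keeps synthetic columns free of
    chance >3-SD cells so the outlier filter only fires on injected cells."""
    x = rng.standard_normal(size)
    while True:
        bad = np.abs(x) > bound
        if not bad.any():
            return x
        x[bad] = rng.standard_normal(bad.sum())


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _make_confounds(ages: np.ndarray, rng: np.random.Generator) -> ConfoundTable:
    n = len(ages)
    z_age = _standardize(ages)
    cols = {}
    cols["sex"] = rng.integers(0, 2, size=n).astype(float)
    for name in CONFOUND_COLUMNS[1:]:
        r = _CONFOUND_AGE_R[name]
        loc, scale = _CONFOUND_LOC_SCALE[name]
        noise = _truncnorm(rng, n)
        cols[name] = loc + scale * (r * z_age + np.sqrt(1.0 - r**2) * noise)
    df = pd.DataFrame(cols, index=[f"sub-{i:04d}" for i in range(n)])
    return ConfoundTable(df)


def generate_cohort(spec: CohortSpec, connectomes: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort from ``spec``.

    The latent axis is the negative squared distance of age from
    ``latent_peak_age``, standardized; behavior variable ``j`` is
    ``beta_j * latent + gamma_j . confounds_z + eps`` with ``eps`` uniform
    noise of SD ``noise_sd``. Missing cells are MCAR; ``n_dead_vars``
    columns are forced above 50% missingness and ``n_outlier_cells`` cells
    in distinct clean columns are pushed beyond 3 SD to exercise the
    quality filters downstream.
    """
    spec.validate()
    rng_age, rng_conf, rng_beh, rng_miss, rng_out, rng_net = _streams(spec.seed, 6)

    ages = _binned_ages(spec, rng_age)
    latent = _standardize(-((ages - spec.latent_peak_age) ** 2))
    confounds = _make_confounds(ages, rng_conf)
    c = confounds.values.to_numpy(dtype=float)
    conf_z = (c - c.mean(axis=0)) / c.std(axis=0)

    m = spec.n_behavior_vars
    n = spec.n_subjects
    n_pos = int(round(spec.frac_increasing * m))
    signs = np.concatenate([np.ones(n_pos), -np.ones(m - n_pos)])
    rng_beh.shuffle(signs)
    beta = signs * np.clip(
        rng_beh.normal(spec.coupling_mean, spec.coupling_sd, size=m), 0.05, None
    )
    gamma = rng_beh.normal(0.0, 0.1, size=(conf_z.shape[1], m))
    # uniform residual noise: bounded, so no clean column trips the 3-SD filter
    eps = rng_beh.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n, m)) * spec.noise_sd
    signal = latent[:, None] * beta[None, :] + conf_z @ gamma
    values = signal + eps

    # missingness pattern decided up front so column statistics below are
    # the ones the downstream quality filter will see
    miss = np.zeros((n, m), dtype=bool)
    if spec.missing_rate > 0:
        miss |= rng_miss.random((n, m)) < spec.missing_rate
    dead_vars = list(rng_miss.choice(m, size=spec.n_dead_vars, replace=False))
    for j in dead_vars:
        frac = rng_miss.uniform(0.55, 0.8)
        rows = rng_miss.choice(n, size=int(np.ceil(frac * n)), replace=False)
        miss[rows, j] = True

    # clean columns must not trip the 3-SD outlier filter by chance: cells
    # whose observed z-score strays beyond 2.9 get their residual noise
    # redrawn (the column still equals signal + eps exactly)
    if spec.noise_sd > 0:
        n_obs = (~miss).sum(axis=0)
        for _ in range(100):
            obs = np.where(miss, np.nan, values)
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.nanmean(obs, axis=0)
                sd = np.nanstd(obs, axis=0, ddof=1)
                sd = np.where(n_obs < 3, np.inf, sd)  # too few cells to call outliers
                bad = (np.abs((obs - mu) / sd) > 2.9) & ~miss
            if not bad.any():
                break
            eps_new = rng_beh.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=int(bad.sum())) * spec.noise_sd
            values[bad] = signal[bad] + eps_new

    var_ids = [f"beh-{j:03d}" for j in range(m)]
    df = pd.DataFrame(np.where(miss, np.nan, values),
                      index=confounds.values.index, columns=var_ids)

    # extreme outliers in distinct clean columns (guaranteed |z| > 3 after injection)
    clean = np.setdiff1d(np.arange(m), np.array(dead_vars, dtype=int))
    if spec.n_outlier_cells > len(clean):
        raise ValueError("n_outlier_cells exceeds the number of clean variables")
    outlier_cols = list(rng_out.choice(clean, size=spec.n_outlier_cells, replace=False))
    for j in outlier_cols:
        col = df.iloc[:, j]
        obs = np.flatnonzero(col.notna().to_numpy())
        i = int(rng_out.choice(obs))
        sign = 1.0 if rng_out.random() < 0.5 else -1.0
        mult = 8.0
        while True:
            injected = col.mean() + sign * mult * col.std()
            trial = col.copy()
            trial.iloc[i] = injected
            if abs((injected - trial.mean()) / trial.std()) > 3.0:
                break
            mult *= 1.5
        df.iloc[i, j] = injected

    domains = pd.Series(
        [BEHAVIOR_DOMAINS[k] for k in _partition_labels(m, len(BEHAVIOR_DOMAINS))],
        index=var_ids,
    )
    behavior = SubjectFeatureTable(df, domains)

    truth = {
        "latent_peak_age": spec.latent_peak_age,
        "latent_model": "standardized -(age - peak)^2",
        "beta": beta.tolist(),
        "gamma": gamma.tolist(),
        "dead_vars": [var_ids[j] for j in dead_vars],
        "outlier_vars": [var_ids[j] for j in outlier_cols],
        "confound_age_r": dict(_CONFOUND_AGE_R),
    }

    cohort = SyntheticCohort(
        ages=ages, latent=latent, confounds=confounds, behavior=behavior,
        connectomes=None, truth=truth,
    )
    if connectomes:
        cohort.connectomes = generate_connectomes(cohort, spec, rng=rng_net)
    return cohort


def generate_connectomes(
    cohort: SyntheticCohort, spec: CohortSpec, rng: np.random.Generator | None = None
) -> ConnectomeStack:
    """Symmetric integer streamline-count matrices with an age-coupled core.

    A fixed group topology is built once: a designated high-degree core
    (the fraction of nodes that downstream rich-club partitioning expects),
    moderately connected periphery, a sparse set of absent edges and a
    configurable subset of rare edges that appear in fewer than half the
    subjects.  Subject ``i`` scales every expected count by
    ``1 + degree_coupling * latent_i`` (floored at 0.05) and counts are
    Poisson around the expectation, so mean degree follows the latent
    inverted-U over age when ``degree_coupling > 0``.
    """
    spec.validate()
    if spec.n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if rng is None:
        rng = _streams(spec.seed, 6)[5]

    nn = spec.n_nodes
    n_core = max(1, int(round(nn * 54 / 376)))
    core = np.arange(n_core)  # first nodes are the planted high-degree core
    iu = np.triu_indices(nn, k=1)
    lam = np.zeros((nn, nn))
    is_core = np.zeros(nn, bool)
    is_core[core] = True

    cc = is_core[iu[0]] & is_core[iu[1]]
    cp = is_core[iu[0]] ^ is_core[iu[1]]
    pp = ~(cc | cp)
    base = np.zeros(len(iu[0]))
    base[cc] = 30.0
    base[cp] = 12.0
    # periphery-periphery: half the pairs connected at moderate rate, rest absent
    pp_idx = np.flatnonzero(pp)
    on = rng.random(len(pp_idx)) < 0.5
    base[pp_idx[on]] = 6.0
    # rare edges: low expectation => present in <50% of subjects
    n_rare = int(round(spec.rare_edge_frac * len(base)))
    rare = rng.choice(np.flatnonzero(base > 0), size=min(n_rare, int((base > 0).sum())), replace=False)
    base[rare] = 0.5
    lam[iu] = base
    lam = lam + lam.T

    voxels = rng.integers(150, 900, size=nn)
    scale = np.clip(1.0 + spec.degree_coupling * cohort.latent, 0.05, None)
    counts = np.zeros((spec.n_subjects, nn, nn), dtype=np.int64)
    for i in range(spec.n_subjects):
        upper = rng.poisson(lam[iu] * scale[i])
        mat = np.zeros((nn, nn), dtype=np.int64)
        mat[iu] = upper
        counts[i] = mat + mat.T

    node_ids = [f"node-{k:03d}" for k in range(nn)]
    stack = ConnectomeStack(counts=counts, voxel_counts=voxels, node_ids=node_ids)
    cohort.truth.setdefault("connectome", {}).update(
        {"core_nodes": core.tolist(), "degree_coupling": spec.degree_coupling}
    )
    return stack


def _partition_labels(n_items: int, n_groups: int) -> np.ndarray:
    """Contiguous near-equal partition of n_items into n_groups (sizes differ by <=1)."""
    if n_items < n_groups:
        raise ValueError(f"cannot partition {n_items} items into {n_groups} nonempty groups")
    base, rem = divmod(n_items, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    return np.repeat(np.arange(n_groups), sizes)


def generate_label_maps(spec: CohortSpec) -> tuple[pd.Series, pd.Series]:
    """Node -> functional-network module map and behavior-variable -> domain map.

    Nodes are partitioned into 10 modules (7 cortical functional networks
    plus hippocampus, amygdala and a combined subcortical group); behavior
    variables into 7 domains.  When the cohort is large enough the three
    non-cortical groups get fixed small sizes (2, 2, 6 nodes) mirroring a
    10-region subcortical complement; otherwise all 10 are near-equal.
    """
    nn, m = spec.n_nodes, spec.n_behavior_vars
    node_ids = [f"node-{k:03d}" for k in range(nn)]
    if nn >= 26:
        tail_sizes = {"hippocampus": 2, "amygdala": 2, "subcortical": 6}
        n_cortex = nn - sum(tail_sizes.values())
        cortex_labels = [NODE_MODULES[g] for g in _partition_labels(n_cortex, 7)]
        tail_labels = [name for name, s in tail_sizes.items() for _ in range(s)]
        labels = cortex_labels + tail_labels
    else:
        labels = [NODE_MODULES[g] for g in _partition_labels(nn, len(NODE_MODULES))]
    node_map = pd.Series(labels, index=node_ids, name="module")

    var_ids = [f"beh-{j:03d}" for j in range(m)]
    domain_map = pd.Series(
        [BEHAVIOR_DOMAINS[g] for g in _partition_labels(m, len(BEHAVIOR_DOMAINS))],
        index=var_ids, name="domain",
    )
    return node_map, domain_map


# ---------------------------------------------------------------------------
# calibration cohorts with exactly planted correlations


def _orthonormal_noise(rng: np.random.Generator, n: int, against: np.ndarray) -> np.ndarray:
    """Unit-variance noise empirically orthogonal to the given columns."""
    g = rng.standard_normal(n)
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), against]))
    g = g - q @ (q.T @ g)
    return _standardize(g)


def planted_axis_cohort(
    n_subjects: int = 600,
    n_vars: tuple[int, int] = (40, 40),
    cross_rho: float = 0.6,
    latent_age_r: float = 0.65,
    age_range: tuple[float, float] = (18.0, 88.0),
    loading: float = 0.8,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> tuple[SubjectFeatureTable, SubjectFeatureTable, np.ndarray, dict]:
    """Two-view cohort with a single latent axis and exactly planted correlations.

    ``cross_rho`` is the in-sample correlation between the two per-view
    latents (the population canonical correlation of the two views), and
    ``latent_age_r`` the correlation with age achievable by the best linear
    combination of the two view latents (what the age regression on the
    first canonical pair should recover).  Noise components are empirically
    orthogonalized so the planted values hold exactly in-sample; variable
    noise then attenuates what any estimator can recover, slightly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    spec = CohortSpec(n_subjects=n_subjects, age_range=age_range, seed=seed)
    ages = _binned_ages(spec, rng)
    z_age = _standardize(ages)

    # corr(best combo of view latents, age) = c * sqrt(2 rho / (1 + rho))
    gain = np.sqrt(2.0 * cross_rho / (1.0 + cross_rho))
    c = latent_age_r / gain
    if not (0.0 <= c <= 1.0):
        raise ValueError("latent_age_r not achievable at this cross_rho")
    g = _orthonormal_noise(rng, n_subjects, z_age[:, None])
    u = c * z_age + np.sqrt(1.0 - c**2) * g

    a = np.sqrt(cross_rho)
    e1 = _orthonormal_noise(rng, n_subjects, np.column_stack([z_age, u]))
    e2 = _orthonormal_noise(rng, n_subjects, np.column_stack([z_age, u, e1]))
    lat1 = a * u + np.sqrt(1.0 - cross_rho) * e1
    lat2 = a * u + np.sqrt(1.0 - cross_rho) * e2

    tables = []
    for view, lat in enumerate((lat1, lat2)):
        mm = n_vars[view]
        loads = loading * np.where(np.arange(mm) % 2 == 0, 1.0, -1.0)
        eps = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n_subjects, mm)) * noise_sd
        vals = lat[:, None] * loads[None, :] + eps
        ids = [f"v{view + 1}-{j:03d}" for j in range(mm)]
        df = pd.DataFrame(vals, index=[f"sub-{i:04d}" for i in range(n_subjects)], columns=ids)
        dom = pd.Series(["view1" if view == 0 else "view2"] * mm, index=ids)
        tables.append(SubjectFeatureTable(df, dom))

    truth = {
        "cross_rho": cross_rho,
        "latent_age_r": latent_age_r,
        "latent_age_component": c,
        "view_latents": np.column_stack([lat1, lat2]),
        "shared_latent": u,
    }
    return tables[0], tables[1], ages, truth


def module_coupled_cohort(
    n_subjects: int = 400,
    n_behavior_vars: int = 70,
    n_network_vars: int = 100,
    coupled_domains: tuple[str, ...] = ("memory", "attention"),
    coupled_modules: tuple[str, ...] = ("visual", "frontoparietal"),
    coupling: float = 0.9,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> dict:
    """Cohort whose only cross-domain coupling is a linear function of age.

    Variables in the chosen behavior domains and network modules load on a
    shared latent equal to standardized age; all other variables are pure
    noise.  Regressing age out of both domains before dimensionality
    reduction must therefore destroy the cross-domain association — the
    mirror experiment for the age-deconfounded model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    spec = CohortSpec(
        n_subjects=n_subjects, n_behavior_vars=n_behavior_vars, n_nodes=n_network_vars,
        seed=seed,
    )
    ages = _binned_ages(spec, rng)
    u = _standardize(ages)
    node_map, domain_map = generate_label_maps(spec)

    subj = [f"sub-{i:04d}" for i in range(n_subjects)]

    def build(ids, labels, coupled_labels):
        mm = len(ids)
        loads = np.zeros(mm)
        coupled = np.isin(labels.to_numpy(), coupled_labels)
        loads[coupled] = coupling * np.where(np.arange(coupled.sum()) % 2 == 0, 1.0, -1.0)
        eps = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n_subjects, mm)) * noise_sd
        eps[:, ~coupled] = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n_subjects, (~coupled).sum()))
        vals = u[:, None] * loads[None, :] + eps
        return SubjectFeatureTable(pd.DataFrame(vals, index=subj, columns=ids), labels)

    behavior = build(list(domain_map.index), domain_map, coupled_domains)
    network = build(list(node_map.index), node_map, coupled_modules)
    return {
        "behavior": behavior,
        "network": network,
        "ages": ages,
        "node_map": node_map,
        "domain_map": domain_map,
        "coupled_domains": coupled_domains,
        "coupled_modules": coupled_modules,
    }


# ---------------------------------------------------------------------------
# plain-text serialization


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as plain text: TSV tables, one matrix file per subject,
    label maps and the truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beh = cohort.behavior.values.copy()
    beh.index.name = "subject"
    beh.to_csv(outdir / "behavior.tsv", sep="\t", na_rep="")
    conf = cohort.confounds.values.copy()
    conf.index.name = "subject"
    conf.to_csv(outdir / "confounds.tsv", sep="\t")
    pd.DataFrame({"subject": beh.index, "age": cohort.ages}).to_csv(
        outdir / "ages.tsv", sep="\t", index=False
    )
    cohort.behavior.variable_domains.rename("domain").rename_axis("variable").to_csv(
        outdir / "behavior_domains.tsv", sep="\t"
    )
    if cohort.connectomes is not None:
        mdir = outdir / "connectomes"
        mdir.mkdir(exist_ok=True)
        for i, sid in enumerate(beh.index):
            np.savetxt(mdir / f"{sid}.txt", cohort.connectomes.counts[i], fmt="%d")
        pd.DataFrame(
            {"node": cohort.connectomes.node_ids, "voxels": cohort.connectomes.voxel_counts}
        ).to_csv(outdir / "voxel_counts.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)


def read_feature_table(path: str | Path, domain_path: str | Path | None = None) -> SubjectFeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if domain_path is not None:
        dom = pd.read_csv(domain_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        dom = pd.Series(["unknown"] * df.shape[1], index=df.columns)
    return SubjectFeatureTable(df, dom)


def read_connectomes(matrix_dir: str | Path, voxel_path: str | Path) -> ConnectomeStack:
    matrix_dir = Path(matrix_dir)
    files = sorted(matrix_dir.glob("*.txt"))
    if not files:
        raise FileNotFoundError(f"no connectome matrices under {matrix_dir}")
    counts = np.stack([np.loadtxt(f, dtype=np.int64) for f in files])
    vox = pd.read_csv(voxel_path, sep="\t")
    return ConnectomeStack(
        counts=counts, voxel_counts=vox["voxels"].to_numpy(), node_ids=list(vox["node"])
    )
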