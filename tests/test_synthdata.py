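import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lifespan_cca import synthdata as sd


def test_ages_evenly_binned_exact_division():
    spec = sd.CohortSpec(n_subjects=140, n_age_bins=7, seed=0)
    cohort = sd.generate_cohort(spec, connectomes=False)
    edges = np.linspace(*spec.age_range, 8)
    counts = np.histogram(cohort.ages, bins=edges)[0]
    assert list(counts) == [20] * 7
    assert cohort.ages.min() >= 18 and cohort.ages.max() <= 88


@given(n=st.integers(20, 300), bins=st.integers(2, 9))
@settings(max_examples=20, deadline=None)
def test_age_bin_balance_property(n, bins):
    spec = sd.CohortSpec(n_subjects=n, n_age_bins=bins, n_behavior_vars=10,
                         n_dead_vars=0, n_outlier_cells=0, seed=3)
    cohort = sd.generate_cohort(spec, connectomes=False)
    edges = np.linspace(*spec.age_range, bins + 1)
    counts = np.histogram(cohort.ages, bins=edges)[0]
    assert counts.max() - counts.min() <= 1
    assert counts.sum() == n


def test_seed_determinism(small_cohort):
    spec, cohort = small_cohort
    again = sd.generate_cohort(spec)
    pd.testing.assert_frame_equal(cohort.behavior.values, again.behavior.values)
    pd.testing.assert_frame_equal(cohort.confounds.values, again.confounds.values)
    assert np.array_equal(cohort.connectomes.counts, again.connectomes.counts)
    assert np.array_equal(cohort.ages, again.ages)


def test_noiseless_cohort_equals_planted_model():
    spec = sd.CohortSpec(n_subjects=60, n_behavior_vars=10, n_nodes=10,
                         noise_sd=0.0, missing_rate=0.0,
                         n_dead_vars=0, n_outlier_cells=0, seed=3)
    c = sd.generate_cohort(spec, connectomes=False)
    conf = c.confounds.values.to_numpy(dtype=float)
    conf_z = (conf - conf.mean(0)) / conf.std(0)
    beta = np.array(c.truth["beta"])
    gamma = np.array(c.truth["gamma"])
    expected = c.latent[:, None] * beta[None, :] + conf_z @ gamma
    assert np.abs(expected - c.behavior.values.to_numpy()).max() == 0.0


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        sd.CohortSpec(n_behavior_vars=3, n_dead_vars=5).validate()
    with pytest.raises(ValueError):
        sd.CohortSpec(age_range=(88.0, 18.0)).validate()
    with pytest.raises(ValueError):
        sd.CohortSpec(frac_increasing=1.5).validate()
    with pytest.raises(ValueError):
        spec = sd.CohortSpec(n_subjects=20, n_nodes=1, n_behavior_vars=5,
                             n_dead_vars=0, n_outlier_cells=0)
        c = sd.generate_cohort(spec, connectomes=False)
        sd.generate_connectomes(c, spec)


def test_connectomes_symmetric_zero_diagonal(small_cohort):
    _, cohort = small_cohort
    counts = cohort.connectomes.counts
    assert np.array_equal(counts, np.swapaxes(counts, 1, 2))
    assert (counts >= 0).all()
    for i in range(counts.shape[0]):
        assert np.diagonal(counts[i]).sum() == 0


def test_confounds_complete_and_weakly_age_correlated(small_cohort):
    _, cohort = small_cohort
    conf = cohort.confounds.values
    assert not conf.isna().any().any()
    for col in conf.columns:
        r = np.corrcoef(conf[col], cohort.ages)[0, 1]
        assert abs(r) <= 0.45  # target |r| <= 0.3 plus sampling noise


def test_null_degree_coupling_decouples_age():
    spec = sd.CohortSpec(n_subjects=200, n_behavior_vars=10, n_nodes=30,
                         n_dead_vars=0, n_outlier_cells=0,
                         degree_coupling=0.0, seed=5)
    c = sd.generate_cohort(spec)
    total = c.connectomes.counts.sum(axis=(1, 2))
    assert abs(np.corrcoef(total, c.latent)[0, 1]) < 0.2


def test_degree_coupling_tracks_latent():
    spec = sd.CohortSpec(n_subjects=300, n_behavior_vars=10, n_nodes=40,
                         n_dead_vars=0, n_outlier_cells=0,
                         degree_coupling=0.5, seed=6)
    c = sd.generate_cohort(spec)
    total = c.connectomes.counts.sum(axis=(1, 2))
    assert np.corrcoef(total, c.latent)[0, 1] > 0.4


def test_rare_edges_fail_consensus(small_cohort):
    _, cohort = small_cohort
    counts = cohort.connectomes.counts
    present = (counts > 0).mean(axis=0)
    iu = np.triu_indices(counts.shape[1], k=1)
    frac = present[iu]
    assert ((frac > 0) & (frac < 0.5)).sum() > 0  # exercises consensus threshold


def test_label_maps_partition():
    spec = sd.CohortSpec(n_nodes=376, n_behavior_vars=334)
    node_map, domain_map = sd.generate_label_maps(spec)
    assert len(node_map) == 376 and node_map.nunique() == 10
    assert len(domain_map) == 334 and domain_map.nunique() == 7
    # exactly one label per item is structural: the maps are Series over all ids
    assert node_map.index.is_unique and domain_map.index.is_unique
    assert (node_map == "hippocampus").sum() == 2
    assert (node_map == "subcortical").sum() == 6


def test_planted_axis_cohort_exact_in_sample_values(planted):
    D1, D2, ages, truth = planted
    lat = truth["view_latents"]
    assert abs(np.corrcoef(lat[:, 0], lat[:, 1])[0, 1] - 0.6) < 1e-10
    # best linear combination of the two view latents correlates with age at 0.65
    A = np.column_stack([lat, np.ones(len(ages))])
    beta, *_ = np.linalg.lstsq(A, ages, rcond=None)
    assert abs(np.corrcoef(A @ beta, ages)[0, 1] - 0.65) < 1e-10


def test_strong_coupling_recoverable():
    spec = sd.CohortSpec(n_subjects=300, n_behavior_vars=20, noise_sd=0.1,
                         n_dead_vars=0, n_outlier_cells=0, missing_rate=0.0, seed=8)
    c = sd.generate_cohort(spec, connectomes=False)
    beta = np.array(c.truth["beta"])
    j = int(np.argmax(np.abs(beta)))
    r = np.corrcoef(c.behavior.values.iloc[:, j], c.latent)[0, 1]
    assert abs(r) > 0.8


def test_roundtrip_io(tmp_path, small_cohort):
    _, cohort = small_cohort
    sd.write_cohort(cohort, tmp_path)
    beh = sd.read_feature_table(tmp_path / "behavior.tsv", tmp_path / "behavior_domains.tsv")
    pd.testing.assert_frame_equal(beh.values, cohort.behavior.values, check_names=False)
    stack = sd.read_connectomes(tmp_path / "connectomes", tmp_path / "voxel_counts.tsv")
    assert np.array_equal(stack.counts, cohort.connectomes.counts)
    assert np.array_equal(stack.voxel_counts, cohort.connectomes.voxel_counts)
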