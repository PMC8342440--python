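import numpy as np
import pandas as pd
import pytest

from lifespan_cca import prep
from lifespan_cca.synthdata import SubjectFeatureTable


def _table(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"v{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=ids)
    return SubjectFeatureTable(df, pd.Series(["d"] * arr.shape[1], index=ids))


def test_filter_drops_outlier_variable(rng):
    x = rng.standard_normal((60, 3)) * 0.5
    x[:, 1] = rng.uniform(-1, 1, 60)
    t = _table(x)
    t.values.iloc[5, 1] = t.values.iloc[:, 1].mean() + 5 * t.values.iloc[:, 1].std()
    filtered, report = prep.filter_variables(t)
    assert "v1" not in filtered.variable_ids
    assert report.set_index("variable").loc["v1", "reason"] == "outlier"


def test_filter_drops_mostly_missing_variable(rng):
    x = rng.uniform(-1, 1, (50, 2))
    t = _table(x)
    t.values.iloc[:30, 0] = np.nan  # 60% missing
    filtered, report = prep.filter_variables(t)
    assert "v0" not in filtered.variable_ids
    assert report.set_index("variable").loc["v0", "reason"] == "missingness"


def test_filter_counts_match_generator_truth(small_cohort):
    spec, cohort = small_cohort
    filtered, report = prep.filter_variables(cohort.behavior)
    # independent recount from the truth record: 5 dead + 3 outlier columns
    expected = set(cohort.truth["dead_vars"]) | set(cohort.truth["outlier_vars"])
    assert set(report["variable"]) == expected
    assert len(report) == spec.n_dead_vars + spec.n_outlier_cells == 8
    assert filtered.values.shape[1] == spec.n_behavior_vars - 8


def test_filter_all_removed_errors():
    t = _table(np.ones((10, 2)))  # constant columns
    with pytest.raises(ValueError):
        prep.filter_variables(t)


def test_zscore_sample_sd_convention():
    t = _table(np.array([[1.0], [2.0], [3.0]]))
    z, stats = prep.zscore(t)
    assert np.allclose(z.values.to_numpy().ravel(), [-1.0, 0.0, 1.0])
    z2, _ = prep.zscore(z)
    assert np.allclose(z.values.to_numpy(), z2.values.to_numpy(), atol=1e-10)


def test_zscore_missing_aware(rng):
    x = rng.uniform(0, 2, (40, 2))
    t = _table(x)
    t.values.iloc[3:9, 0] = np.nan
    z, _ = prep.zscore(t)
    col = z.values.iloc[:, 0]
    assert col.isna().sum() == 6
    assert col.mean() == pytest.approx(0.0, abs=1e-10)
    assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_zscore_zero_variance_named():
    t = _table(np.column_stack([np.ones(10), np.arange(10.0)]), ids=["flat", "ok"])
    with pytest.raises(ValueError, match="flat"):
        prep.zscore(t)


def test_deconfound_removes_confound_exactly(rng):
    conf = pd.DataFrame({"c1": rng.standard_normal(80)})
    t = _table(conf["c1"].to_numpy().reshape(-1, 1) * 2.0 + 1.0)
    resid, _ = prep.deconfound(t, conf)
    assert np.abs(resid.values.to_numpy()).max() < 1e-10


def test_deconfound_residuals_orthogonal_and_idempotent(rng):
    conf = pd.DataFrame(rng.standard_normal((120, 3)), columns=list("abc"))
    t = _table(rng.standard_normal((120, 4)))
    resid, model = prep.deconfound(t, conf)
    R = resid.values.to_numpy()
    for j in range(3):
        c = conf.iloc[:, j] - conf.iloc[:, j].mean()
        r = np.abs(R.T @ c) / (np.linalg.norm(R, axis=0) * np.linalg.norm(c))
        assert r.max() < 1e-8
    resid2, _ = prep.deconfound(resid, conf)
    assert np.allclose(R, resid2.values.to_numpy(), atol=1e-8)


def test_deconfound_age_removes_linear_component_only(rng):
    age = np.linspace(18, 88, 150)
    quad = (age - 40.0) ** 2
    t = _table(np.column_stack([quad + rng.normal(0, 1, 150)]))
    resid, _ = prep.deconfound(t, None, extra=age.reshape(-1, 1))
    r = resid.values.to_numpy().ravel()
    ac = age - age.mean()
    assert abs(r @ ac) / (np.linalg.norm(r) * np.linalg.norm(ac)) < 1e-8
    # the quadratic structure survives linear-age removal
    q = quad - np.polyval(np.polyfit(age, quad, 1), age)
    assert np.corrcoef(r, q)[0, 1] > 0.9


def test_deconfound_rank_deficient_errors(rng):
    c = rng.standard_normal(50)
    conf = pd.DataFrame({"a": c, "b": 2 * c})
    with pytest.raises(ValueError):
        prep.deconfound(_table(rng.standard_normal((50, 2))), conf)


def test_nearest_spd_fixed_point(rng):
    x = rng.standard_normal((200, 4))
    cov = np.cov(x, rowvar=False)
    out = prep.nearest_spd_covariance(cov)
    assert np.abs(out - cov).max() < 1e-8


def test_nearest_spd_indefinite_input_matches_eigenclip_oracle():
    A = np.array([[1.0, 1.2], [1.2, 1.0]])  # eigenvalues 2.2 and -0.2
    out = prep.nearest_spd_covariance(A)
    assert np.linalg.eigvalsh(out).min() >= 0
    # Frobenius-nearest PSD matrix of a symmetric matrix is its eigen-clipped form
    w, V = np.linalg.eigh(A)
    oracle = (V * np.maximum(w, 1e-10)) @ V.T
    assert np.abs(out - oracle).max() < 1e-6


def test_nearest_spd_complete_data_equals_sample_covariance(rng):
    t = _table(rng.standard_normal((100, 5)))
    out = prep.nearest_spd_covariance(t)
    assert np.allclose(out, t.values.cov().to_numpy(), atol=1e-8)


def test_pca_orthonormal_and_reconstructs(rng):
    t = _table(rng.standard_normal((50, 6)))
    z, _ = prep.zscore(t)
    basis = prep.pca_basis(z, 6)
    assert np.allclose(basis.components.T @ basis.components, np.eye(6), atol=1e-8)
    recon = basis.scores @ basis.components.T
    assert np.allclose(recon, z.values.to_numpy(), atol=1e-8)
    assert np.allclose(basis.scores.mean(axis=0), 0.0, atol=1e-8)


def test_pca_collinear_data_second_eigenvalue_zero(rng):
    x = rng.standard_normal(80)
    t = _table(np.column_stack([x, 2 * x]))
    basis = prep.pca_basis(t, 2)
    assert basis.explained_variance[1] == pytest.approx(0.0, abs=1e-10)


def test_pca_n_comp_out_of_range(rng):
    t = _table(rng.standard_normal((20, 3)))
    with pytest.raises(ValueError):
        prep.pca_basis(t, 4)


def test_pca_sign_convention_deterministic(rng):
    t = _table(rng.standard_normal((60, 5)))
    b1 = prep.pca_basis(t, 3)
    b2 = prep.pca_basis(t, 3)
    assert np.array_equal(b1.components, b2.components)
    for j in range(3):
        col = b1.components[:, j]
        assert col[np.argmax(np.abs(col))] > 0
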