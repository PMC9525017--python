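import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csvd_brainage as cb
from conftest import random_subjects


def _design(subjects, group):
    covs = cb.build_covariates(subjects)
    X = np.column_stack([np.ones(len(subjects)), group,
                         covs.to_numpy(dtype=float)])
    return covs, X


def test_ancova_matches_normal_equations_oracle(subjects_60):
    """Coefficients, partial SS and the F/t p-value agree with a hand-rolled
    least-squares oracle on a 40-row fixture."""
    rng = np.random.default_rng(1)
    sub = subjects_60.head(40).reset_index(drop=True)
    group = (rng.uniform(size=40) < 0.4).astype(float)
    y = 2.0 * group + 0.1 * sub["age"].to_numpy() + rng.normal(0, 1.5, 40)
    covs, X = _design(sub, group)
    res = cb.ancova_group_effect(y, group, covs)

    # oracle: normal equations + partial F from SSE difference
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    sse_full = float(np.sum((y - X @ beta) ** 2))
    Xr = np.delete(X, 1, axis=1)
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    sse_red = float(np.sum((y - Xr @ br) ** 2))
    dfres = 40 - X.shape[1]
    F = (sse_red - sse_full) / (sse_full / dfres)
    p = float(stats.f.sf(F, 1, dfres))
    assert res.coef == pytest.approx(beta[1], rel=1e-10)
    assert res.pvalue == pytest.approx(p, rel=1e-8)
    assert res.partial_eta_sq == pytest.approx(
        (sse_red - sse_full) / (sse_red - sse_full + sse_full), rel=1e-10)


def test_partial_eta_squared_t_identity(subjects_60):
    """Single-df identity eta^2 = t^2 / (t^2 + df_resid) to 1e-10."""
    rng = np.random.default_rng(2)
    group = (rng.uniform(size=60) < 0.5).astype(float)
    y = group + rng.normal(size=60)
    res = cb.ancova_group_effect(y, group, cb.build_covariates(subjects_60))
    t2 = res.tstat**2
    assert res.partial_eta_sq == pytest.approx(t2 / (t2 + res.df_resid),
                                               abs=1e-10)


def test_outcome_equal_to_covariate_gives_null_group_effect(subjects_60):
    rng = np.random.default_rng(3)
    group = (rng.uniform(size=60) < 0.5).astype(float)
    y = subjects_60["education_years"].to_numpy()
    res = cb.ancova_group_effect(y, group, cb.build_covariates(subjects_60))
    assert res.coef == pytest.approx(0.0, abs=1e-8)
    assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-12)


def test_location_invariance_of_group_test(subjects_60):
    rng = np.random.default_rng(4)
    group = (rng.uniform(size=60) < 0.5).astype(float)
    y = group * 1.5 + rng.normal(size=60)
    covs = cb.build_covariates(subjects_60)
    r1 = cb.ancova_group_effect(y, group, covs)
    r2 = cb.ancova_group_effect(y + 100.0, group, covs)
    assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-9)
    assert r1.partial_eta_sq == pytest.approx(r2.partial_eta_sq, rel=1e-9)


def test_collinear_covariates_error_names_dependency(subjects_60):
    rng = np.random.default_rng(5)
    group = (rng.uniform(size=60) < 0.5).astype(float)
    covs = cb.build_covariates(subjects_60)
    covs["age_copy"] = covs["age"] * 2.0
    with pytest.raises(ValueError, match="age_copy"):
        cb.ancova_group_effect(rng.normal(size=60), group, covs)


def test_constant_inputs_rejected(subjects_60):
    covs = cb.build_covariates(subjects_60)
    with pytest.raises(ValueError, match="group"):
        cb.ancova_group_effect(np.arange(60.0), np.ones(60), covs)
    rng = np.random.default_rng(6)
    group = (rng.uniform(size=60) < 0.5).astype(float)
    with pytest.raises(ValueError, match="constant"):
        cb.ancova_group_effect(np.ones(60), group, covs)


@pytest.mark.parametrize("alpha, k, expected", [
    (0.05, 442, 0.000113),
    (0.05, 1, 0.05),
    (0.01, 4, 0.0025),
])
def test_bonferroni_threshold(alpha, k, expected):
    assert cb.bonferroni_threshold(alpha, k) == pytest.approx(expected,
                                                              abs=5e-7)


def test_bonferroni_threshold_validation():
    with pytest.raises(ValueError, match="k"):
        cb.bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError, match="alpha"):
        cb.bonferroni_threshold(1.5, 10)


def test_null_permutation_p_values_are_uniform(subjects_60):
    """Permuting group labels under the null yields uniform p-values
    (Kolmogorov-Smirnov check at desk scale)."""
    rng = np.random.default_rng(7)
    y = rng.normal(size=60)
    covs = cb.build_covariates(subjects_60)
    base = (np.arange(60) < 25).astype(float)
    ps = []
    for _ in range(200):
        ps.append(cb.ancova_group_effect(y, rng.permutation(base), covs).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_age_squared_is_exact(subjects_60):
    covs = cb.build_covariates(subjects_60)
    assert np.array_equal(covs["age_sq"].to_numpy(),
                          covs["age"].to_numpy() ** 2)


def test_missing_covariate_column_named():
    sub = random_subjects(np.random.default_rng(8), 30).drop(columns=["efc"])
    with pytest.raises(ValueError, match="efc"):
        cb.build_covariates(sub)


def test_regional_comparison_tallies_sum(tiny_atlas, app_config):
    """Compartment tallies of the flagged set sum to its size, and summary
    bookkeeping matches the table."""
    subjects, features, truth = cb.generate_application_cohort(
        app_config, tiny_atlas)
    rng = np.random.default_rng(9)
    rows = []
    for rid in tiny_atlas.region_ids:
        bagv = rng.normal(0, 3, len(subjects)) + \
            truth.extra_aging.get(rid, pd.Series(0, index=truth.extra_aging.index)).to_numpy()
        rows.append(pd.DataFrame({
            "subject_id": subjects["subject_id"], "scope": rid,
            "predicted_age": subjects["age"] + bagv,
            "age": subjects["age"], "bag": bagv}))
    bag = cb.BagResult(table=pd.concat(rows, ignore_index=True))
    res = cb.regional_bag_comparison(bag, subjects, truth.csvd_flag,
                                     tiny_atlas)
    s = res.summary()
    assert s["n_regions"] == tiny_atlas.n_regions
    assert sum(s["significant_by_compartment"].values()) == s["n_significant"]
    assert res.threshold == pytest.approx(0.05 / tiny_atlas.n_regions)
    assert set(res.significant_regions) == \
        set(res.table.loc[res.table["significant"], "region_id"])


def test_cohort_summary_shape(tiny_atlas, app_config):
    subjects, _, truth = cb.generate_application_cohort(app_config, tiny_atlas)
    tab = cb.cohort_summary(subjects, truth.csvd_flag)
    assert {"age", "mmse", "hypertension"} <= set(tab["variable"])
    assert tab["pvalue"].between(0, 1).all()
    assert set(tab["test"]) == {"t", "chi2", "ancova"}
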