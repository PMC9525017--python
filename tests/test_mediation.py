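import numpy as np
import pandas as pd
import pytest

import csvd_brainage as cb
from csvd_brainage.mediation import (_bca_pvalue, bias_constant,
                                     jackknife_acceleration)
from conftest import random_subjects


def _random_input(seed, n=80, a=1.5, b=-0.8, cprime=-0.5, with_covs=True):
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < 0.4).astype(float)
    covs = None
    bg = 0.0
    if with_covs:
        sub = random_subjects(rng, n)
        covs = cb.build_covariates(sub, include=cb.MEDIATION_COVARIATES)
        bg = -0.03 * covs["age"].to_numpy() + 0.1 * covs["education_years"].to_numpy()
    m = a * x + rng.normal(size=n) + (0.05 * covs["age"].to_numpy() if with_covs else 0)
    y = b * m + cprime * x + bg + rng.normal(size=n)
    return cb.MediationInput(x=x, m=m, y=y, covariates=covs)


@pytest.mark.parametrize("seed", range(8))
def test_total_effect_decomposition_identity(seed):
    """c = c' + a*b holds to 1e-10 for nested least squares with a shared
    covariate set, with and without covariates."""
    inp = _random_input(seed, with_covs=bool(seed % 2))
    p = cb.fit_mediation_paths(inp)
    assert abs(p.c - (p.cprime + p.ab)) <= 1e-10 * max(1.0, abs(p.c))


def test_paths_match_normal_equations_oracle():
    """a, b, c, c' equal an independent normal-equations solve on a 30-row
    fixture (raw, unstandardised designs)."""
    inp = _random_input(123, n=30)
    p = cb.fit_mediation_paths(inp)
    n = inp.n
    Z = inp.covariates.to_numpy(dtype=float)
    D1 = np.column_stack([inp.x, np.ones(n), Z])
    D3 = np.column_stack([inp.x, inp.m, np.ones(n), Z])
    c1 = np.linalg.solve(D1.T @ D1, D1.T @ inp.m)
    c2 = np.linalg.solve(D1.T @ D1, D1.T @ inp.y)
    c3 = np.linalg.solve(D3.T @ D3, D3.T @ inp.y)
    assert p.a == pytest.approx(c1[0], rel=1e-8)
    assert p.c == pytest.approx(c2[0], rel=1e-8)
    assert p.cprime == pytest.approx(c3[0], rel=1e-8)
    assert p.b == pytest.approx(c3[1], rel=1e-8)


def test_covariate_inclusion_equals_frisch_waugh_residualisation():
    """Pre-residualising X, M, Y on the covariates and refitting without
    them reproduces the same path point estimates (FWL theorem)."""
    inp = _random_input(7, n=100)
    p = cb.fit_mediation_paths(inp)
    n = inp.n
    Z = np.column_stack([np.ones(n), inp.covariates.to_numpy(dtype=float)])
    H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    rx, rm, ry = inp.x - H @ inp.x, inp.m - H @ inp.m, inp.y - H @ inp.y
    q = cb.fit_mediation_paths(cb.MediationInput(x=rx, m=rm, y=ry))
    assert q.a == pytest.approx(p.a, rel=1e-8)
    assert q.b == pytest.approx(p.b, rel=1e-8)
    assert q.c == pytest.approx(p.c, rel=1e-8)
    assert q.cprime == pytest.approx(p.cprime, rel=1e-8)


def test_null_path_a_estimate_within_sampling_error():
    rng = np.random.default_rng(11)
    n = 150
    x = (rng.uniform(size=n) < 0.5).astype(float)
    m = rng.normal(size=n)  # independent of x
    y = -0.5 * m + rng.normal(size=n)
    p = cb.fit_mediation_paths(cb.MediationInput(x=x, m=m, y=y))
    assert abs(p.a) < 3.5 * p.se_a


def test_rank_deficient_design_names_column():
    rng = np.random.default_rng(12)
    n = 40
    x = (rng.uniform(size=n) < 0.5).astype(float)
    covs = pd.DataFrame({"z1": rng.normal(size=n)})
    covs["z2"] = 2.0 * covs["z1"]
    with pytest.raises(ValueError, match="z2"):
        cb.fit_mediation_paths(cb.MediationInput(
            x=x, m=rng.normal(size=n), y=rng.normal(size=n), covariates=covs))


def test_constant_exposure_rejected():
    with pytest.raises(ValueError, match="constant"):
        cb.MediationInput(x=np.ones(10), m=np.zeros(10), y=np.zeros(10))


# ------------------------------------------------------------ BCa mechanics

def test_bca_reduces_to_percentile_interval_when_unbiased():
    rng = np.random.default_rng(13)
    samples = rng.normal(2.0, 1.0, 4000)
    lo, hi = cb.bca_interval(samples, 2.0, alpha=0.05, z0=0.0, ahat=0.0)
    assert lo == pytest.approx(np.quantile(samples, 0.025))
    assert hi == pytest.approx(np.quantile(samples, 0.975))


def test_bca_hand_worked_ten_sample_example():
    """B = 10 worked example: z0 and the interval endpoints match a manual
    calculation (frozen values)."""
    samples = np.array([1.2, 1.5, 1.9, 2.1, 2.3, 2.6, 3.0, 3.4, 3.9, 4.5])
    theta_hat = 2.8  # 6 of 10 bootstrap values lie below
    z0 = bias_constant(samples, theta_hat)
    assert z0 == pytest.approx(0.2533471031, abs=1e-9)  # Phi^-1(0.6)
    lo, hi = cb.bca_interval(samples, theta_hat, alpha=0.10, z0=z0, ahat=0.1)
    assert lo == pytest.approx(1.6993155992, abs=1e-9)
    assert hi == pytest.approx(4.4745557292, abs=1e-9)


def test_bias_constant_clamps_one_sided_distributions():
    with pytest.warns(RuntimeWarning, match="clamped"):
        z0 = bias_constant(np.arange(10.0), 100.0)
    assert np.isfinite(z0)


def test_jackknife_acceleration_zero_for_symmetric_values():
    assert jackknife_acceleration(np.array([1.0, 2.0, 3.0])) == 0.0
    assert jackknife_acceleration(np.full(5, 2.0)) == 0.0


def test_inversion_pvalue_consistent_with_interval_coverage():
    """The inversion p-value is below alpha exactly when the BCa interval
    at that alpha excludes zero."""
    rng = np.random.default_rng(14)
    for shift in (0.2, 0.8, 2.0):
        samples = rng.normal(shift, 1.0, 2000)
        theta = shift
        z0 = bias_constant(samples, theta)
        p = _bca_pvalue(samples, z0, 0.0)
        for alpha in (0.01, 0.05, 0.2):
            lo, hi = cb.bca_interval(samples, theta, alpha, z0, 0.0)
            excludes = lo > 0 or hi < 0
            assert (p < alpha) == excludes


# ------------------------------------------------------------ bootstrap

def test_bootstrap_reproducible_under_fixed_seed():
    inp = _random_input(21, n=60)
    r1 = cb.bootstrap_mediation(inp, B=400, seed=5)
    r2 = cb.bootstrap_mediation(inp, B=400, seed=5)
    assert r1.p_ab == r2.p_ab and r1.ci == r2.ci
    r3 = cb.bootstrap_mediation(inp, B=400, seed=6)
    assert r3.p_ab != r1.p_ab or r3.ci != r1.ci


def test_bootstrap_detects_planted_indirect_effect():
    inp = _random_input(22, n=200, a=2.0, b=-1.0, cprime=-0.5)
    res = cb.bootstrap_mediation(inp, B=1000, seed=0)
    assert res.p_ab < 0.01
    assert res.ci["ab"][1] < 0
    assert res.significant


def test_bc_switch_drops_acceleration():
    inp = _random_input(23, n=80)
    acc = cb.bootstrap_mediation(inp, B=400, seed=1, accelerated=True)
    plain = cb.bootstrap_mediation(inp, B=400, seed=1, accelerated=False)
    assert not plain.accelerated
    # same resamples, different interval adjustment (generically)
    assert plain.paths.ab == acc.paths.ab


def test_rare_exposure_resamples_are_redrawn_not_fatal():
    rng = np.random.default_rng(24)
    n = 12
    x = np.zeros(n)
    x[:2] = 1.0
    m = 1.0 * x + rng.normal(size=n)
    y = 0.5 * m + rng.normal(size=n)
    res = cb.bootstrap_mediation(cb.MediationInput(x=x, m=m, y=y),
                                 B=200, seed=2)
    assert np.isfinite(res.p_ab)


def test_small_b_rejected():
    inp = _random_input(25, n=40)
    with pytest.raises(ValueError, match="B"):
        cb.bootstrap_mediation(inp, B=50)


@pytest.mark.parametrize("ab, c, expected", [
    (0.7, 5.0, 14.0),
    (0.0, 5.0, 0.0),
    (5.0, 5.0, 100.0),
])
def test_proportion_mediated_arithmetic(ab, c, expected):
    value, defined = cb.proportion_mediated(ab, c)
    assert defined and value == pytest.approx(expected)


def test_proportion_mediated_undefined_near_zero_total_effect():
    value, defined = cb.proportion_mediated(0.5, 1e-12)
    assert not defined and np.isnan(value)


# ------------------------------------------------------------ screen

def _screen_setup(seed=31, n=150):
    rng = np.random.default_rng(seed)
    sub = random_subjects(rng, n)
    sub["mmse"] = rng.normal(26, 2, n)
    sub["cvvlt"] = rng.normal(6, 2, n)
    x = (rng.uniform(size=n) < 0.3).astype(float)
    rows = []
    for rid in ("ctx001", "ctx002", "sub001"):
        bagv = rng.normal(0, 3, n)
        rows.append(pd.DataFrame({
            "subject_id": sub["subject_id"], "scope": rid,
            "predicted_age": sub["age"] + bagv, "age": sub["age"],
            "bag": bagv}))
    bag = cb.BagResult(table=pd.concat(rows, ignore_index=True))
    flags = pd.Series(x.astype(bool), index=sub["subject_id"].to_numpy())
    return bag, sub, flags


def test_screen_cardinality_is_regions_times_outcomes():
    bag, sub, flags = _screen_setup()
    tab = cb.mediation_screen(bag, sub, flags, outcomes=("mmse", "cvvlt"),
                              B=200, seed=0)
    assert len(tab) == 3 * 2
    assert set(tab["region_id"]) == {"ctx001", "ctx002", "sub001"}


def test_screen_unknown_outcome_named():
    bag, sub, flags = _screen_setup()
    with pytest.raises(ValueError, match="nonexistent"):
        cb.mediation_screen(bag, sub, flags, outcomes=("nonexistent",), B=200)


def test_screen_unknown_region_named():
    bag, sub, flags = _screen_setup()
    with pytest.raises(ValueError, match="ctx999"):
        cb.mediation_screen(bag, sub, flags, regions=["ctx999"], B=200)


def test_screen_reproducible_and_fwer_column():
    bag, sub, flags = _screen_setup()
    t1 = cb.mediation_screen(bag, sub, flags, B=300, seed=4, fwer=True)
    t2 = cb.mediation_screen(bag, sub, flags, B=300, seed=4, fwer=True)
    pd.testing.assert_frame_equal(t1, t2)
    assert "significant_fwer" in t1.columns
    # FWER flag is never more liberal than the uncorrected flag
    assert not (t1["significant_fwer"] & ~t1["significant"]).any()
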