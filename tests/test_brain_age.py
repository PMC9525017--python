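import numpy as np
import pytest
from sklearn.dummy import DummyRegressor
from sklearn.pipeline import Pipeline

import csvd_brainage as cb
from csvd_brainage.brain_age import age_stratified_folds, select_params, _pipeline


@pytest.mark.parametrize(
    "pred, true, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([6, 7, 8], [1, 2, 3], 5.0),
        ([1.0, 3.0], [2.0, 2.0], 1.0),
    ],
)
def test_mae_definition(pred, true, expected):
    assert cb.mae(pred, true) == pytest.approx(expected)


def test_r_squared_definition():
    true = np.array([1.0, 2.0, 3.0, 4.0])
    assert cb.r_squared(true, true) == pytest.approx(1.0)
    assert cb.r_squared(np.full(4, true.mean()), true) == pytest.approx(0.0)
    with pytest.warns(RuntimeWarning, match="zero variance"):
        assert np.isnan(cb.r_squared(true, np.full(4, 2.0)))


def test_metric_input_validation():
    with pytest.raises(ValueError):
        cb.mae([1, 2], [1])
    with pytest.raises(ValueError):
        cb.r_squared([1.0], [1.0])


def test_noiseless_affine_signal_learned_within_epsilon():
    """An exactly affine age signal is learnable up to the insensitive-loss
    width: pooled out-of-fold MAE <= epsilon + 0.5 y."""
    rng = np.random.default_rng(0)
    age = rng.uniform(18, 92, 120)
    X = np.column_stack([600 - 1.8 * age, 500 - 1.2 * age, 400 - 0.9 * age])
    model = cb.nested_cv_fit(X, age, cb.ModelSpec(seed=0))
    assert model.cv.pooled_mae <= model.spec.epsilon + 0.5
    assert model.cv.pooled_r2 > 0.99


def test_constant_ages_degenerate_target():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    y = np.full(40, 70.0)
    with pytest.warns(RuntimeWarning, match="constant target"):
        model = cb.nested_cv_fit(X, y, cb.ModelSpec(
            c_grid=(1.0,), gamma_grid=(0.1,), seed=0))
    assert np.allclose(model.cv.oof_pred, 70.0, atol=model.spec.epsilon + 1e-6)
    assert model.cv.pooled_mae <= model.spec.epsilon
    assert np.isnan(model.cv.pooled_r2)


def test_too_few_subjects_rejected():
    with pytest.raises(ValueError, match="k_outer"):
        cb.nested_cv_fit(np.zeros((3, 2)), np.arange(3.0), cb.ModelSpec())


def test_constant_feature_column_warns_but_proceeds():
    rng = np.random.default_rng(2)
    age = rng.uniform(20, 90, 60)
    X = np.column_stack([500 - age, np.full(60, 7.0)])
    with pytest.warns(RuntimeWarning, match="constant feature"):
        model = cb.fit_model(X, age, cb.ModelSpec(
            c_grid=(10.0,), gamma_grid=(0.1,), seed=0))
    assert np.isfinite(model.predict(X)).all()


def test_out_of_fold_predictions_respect_fold_membership():
    """Refitting each outer-fold model from the recorded hyperparameters on
    the recorded training folds reproduces the out-of-fold predictions
    exactly, proving no test subject entered its own fit."""
    rng = np.random.default_rng(3)
    age = rng.uniform(18, 92, 80)
    X = np.column_stack([550 - 1.5 * age + rng.normal(0, 8, 80),
                         480 - 1.1 * age + rng.normal(0, 8, 80)])
    spec = cb.ModelSpec(c_grid=(1.0, 10.0, 100.0), gamma_grid=(0.1,), seed=42)
    model = cb.nested_cv_fit(X, age, spec)
    cv = model.cv
    folds = age_stratified_folds(age, spec.k_outer, spec.seed)
    assert sorted(np.concatenate([te for _, te in folds]).tolist()) == list(range(80))
    for i, (tr, te) in enumerate(folds):
        assert np.all(cv.fold_id[te] == i)
        est = _pipeline(spec)
        est.set_params(svr__C=cv.fold_params[i]["C"],
                       svr__gamma=cv.fold_params[i]["gamma"])
        est.fit(X[tr], age[tr])
        assert np.allclose(est.predict(X[te]), cv.oof_pred[te])


def test_grid_selection_matches_manual_enumeration(subjects_60):
    """Implementation's grid search equals an independent loop over all
    (C, gamma) candidates scored fold by fold, including tie-breaking."""
    from sklearn.model_selection import KFold

    rng = np.random.default_rng(9)
    age = subjects_60["age"].to_numpy()
    X = np.column_stack([540 - 1.4 * age, 470 - 0.8 * age]) \
        + rng.normal(0, 6, (60, 2))
    spec = cb.ModelSpec(c_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1, 1.0),
                        seed=5)
    chosen = select_params(X, age, spec)

    best, best_err = None, np.inf
    for C in sorted(spec.c_grid):
        for gamma in sorted(spec.gamma_grid):
            errs = []
            for tr, te in KFold(spec.k_inner, shuffle=True,
                                random_state=spec.seed).split(X):
                est = _pipeline(spec)
                est.set_params(svr__C=C, svr__gamma=gamma)
                est.fit(X[tr], age[tr])
                errs.append(np.mean(np.abs(est.predict(X[te]) - age[te])))
            if np.mean(errs) < best_err:
                best, best_err = {"C": C, "gamma": gamma}, np.mean(errs)
    assert chosen == best


def test_scaling_statistics_come_from_training_data_only():
    rng = np.random.default_rng(4)
    age = rng.uniform(20, 90, 50)
    X = np.column_stack([520 - 1.3 * age, 450 - 0.7 * age])
    model = cb.fit_model(X, age, cb.ModelSpec(
        c_grid=(10.0,), gamma_grid=(0.1,), seed=0))
    scaler = model.estimator.named_steps["scaler"]
    assert np.allclose(scaler.mean_, X.mean(axis=0))
    assert np.allclose(scaler.scale_, X.std(axis=0))
    # manual standardization then bare SVR equals the pipeline prediction
    Xnew = X[:5] + 3.0
    manual = (Xnew - X.mean(axis=0)) / X.std(axis=0)
    svr = model.estimator.named_steps["svr"]
    assert np.allclose(svr.predict(manual), model.predict(Xnew))


def test_prediction_matches_independent_kernel_expansion():
    """Pipeline predictions equal the explicit RBF kernel expansion over
    the support vectors: sum_i alpha_i exp(-gamma ||x - sv_i||^2) + b."""
    rng = np.random.default_rng(5)
    age = rng.uniform(20, 90, 60)
    X = np.column_stack([530 - 1.2 * age + rng.normal(0, 5, 60),
                         490 - 0.9 * age + rng.normal(0, 5, 60)])
    model = cb.fit_model(X, age, cb.ModelSpec(
        c_grid=(100.0,), gamma_grid=(0.1,), seed=0))
    svr = model.estimator.named_steps["svr"]
    scaler = model.estimator.named_steps["scaler"]
    Z = scaler.transform(X)
    gamma = float(svr.gamma)
    sq = ((Z[:, None, :] - svr.support_vectors_[None]) ** 2).sum(-1)
    manual = np.exp(-gamma * sq) @ svr.dual_coef_.ravel() + svr.intercept_[0]
    assert np.allclose(manual, model.predict(X), atol=1e-8)


def test_identical_regions_give_identical_predictions(tiny_atlas):
    rng = np.random.default_rng(6)
    age = rng.uniform(18, 92, 70)
    block = 500 - 1.5 * age[:, None] + rng.normal(0, 8, (70, 4))
    import pandas as pd

    cols = {}
    for rid in tiny_atlas.region_ids:
        for j, c in enumerate(tiny_atlas.voxel_columns(rid)):
            cols[c] = block[:, j]
    fs = cb.FeatureSet(
        voxels=pd.DataFrame(cols, index=[f"S{i}" for i in range(70)]),
        atlas=tiny_atlas,
    )
    spec = cb.ModelSpec(c_grid=(10.0,), gamma_grid=(0.1,), seed=0)
    models = cb.fit_regional_models(fs, age, tiny_atlas, spec, evaluate=False)
    p1 = models["ctx001"].predict(fs.region_block("ctx001").to_numpy())
    p2 = models["ctx002"].predict(fs.region_block("ctx002").to_numpy())
    assert np.allclose(p1, p2)


def test_pure_noise_region_has_near_zero_r2():
    rng = np.random.default_rng(8)
    r2s = []
    for _ in range(3):
        age = rng.uniform(18, 92, 120)
        X = rng.normal(500, 20, size=(120, 4))  # no age signal at all
        model = cb.nested_cv_fit(X, age, cb.ModelSpec(
            c_grid=(1.0, 10.0), gamma_grid=(0.1,), seed=1))
        r2s.append(model.cv.pooled_r2)
    assert -0.35 < float(np.mean(r2s)) < 0.1


def test_bag_is_predicted_minus_chronological():
    est = Pipeline([("svr", DummyRegressor(constant=65.3).fit(
        np.zeros((2, 1)), [65.3, 65.3]))])
    model = cb.BrainAgeModel(estimator=est, feature_names=["ctx001__v000"],
                             spec=cb.ModelSpec())
    atlas = cb.make_atlas(1, 0, 0, voxels_per_region=1)
    import pandas as pd

    fs = cb.FeatureSet(
        voxels=pd.DataFrame({"ctx001__v000": [1.0]}, index=["S0"]), atlas=atlas)
    bag = cb.predict_and_bag(None, {"ctx001": model}, fs, [60.0])
    row = bag.table.iloc[0]
    assert row["bag"] == pytest.approx(5.3)
    assert row["predicted_age"] == pytest.approx(65.3)


def test_schema_mismatch_lists_missing_and_extra_columns():
    import pandas as pd

    rng = np.random.default_rng(10)
    age = rng.uniform(20, 90, 40)
    X = pd.DataFrame({"a": 500 - age, "b": 400 - 0.5 * age})
    model = cb.fit_model(X.to_numpy(), age, cb.ModelSpec(
        c_grid=(10.0,), gamma_grid=(0.1,), seed=0), feature_names=["a", "b"])
    wrong = X.rename(columns={"b": "zz"})
    with pytest.raises(ValueError, match="missing=\\['b'\\].*extra=\\['zz'\\]"):
        model.predict(wrong)
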