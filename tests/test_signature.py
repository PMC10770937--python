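import numpy as np
import pandas as pd
import pytest

from trm_spatial import (
    ImportanceRanking,
    SignatureError,
    SignatureResults,
    SpatialSignatureModel,
    intersect_top10,
    rank_importance,
    score_patients,
    split_cohort,
)
from trm_spatial.signature import METHODS, Preprocessor, _breslow_partial_loglik

from conftest import make_clinical


def _ranking(method, names):
    scores = pd.Series(np.linspace(1, 0, len(names)), index=names)
    return ImportanceRanking.from_scores(method, scores, 10)


def test_split_sizes_and_determinism():
    clin = make_clinical([f"P{i}" for i in range(274)])
    split = split_cohort(clin, seed=42)
    assert len(split.train_ids) == 192 and len(split.test_ids) == 82
    again = split_cohort(clin, seed=42)
    assert split.assignment == again.assignment
    other = split_cohort(clin, seed=43)
    assert split.assignment != other.assignment

    big = split_cohort(make_clinical([f"Q{i}" for i in range(1000)]), seed=0)
    frac = len(big.train_ids) / 1000
    assert 0.69 <= frac <= 0.71


def test_split_warns_below_10_epv():
    clin = make_clinical([f"P{i}" for i in range(40)])
    with pytest.warns(UserWarning, match="EPV"):
        split_cohort(clin, seed=0, n_candidate_features=50)


def _survival_with_signal(rng, n, betas, p_noise):
    """Feature matrix: planted columns + independent noise; exponential PH."""
    X = pd.DataFrame(
        rng.normal(size=(n, len(betas) + p_noise)),
        columns=[f"f{i:02d}" for i in range(len(betas) + p_noise)],
        index=[f"P{i}" for i in range(n)],
    )
    lp = X.iloc[:, : len(betas)].to_numpy() @ np.asarray(betas)
    time = rng.exponential(1.0, size=n) / np.exp(lp - lp.mean())
    censor = rng.uniform(0, np.quantile(time, 0.8), size=n)
    event = time <= censor
    return X, np.minimum(time, censor), event


@pytest.mark.parametrize("method", METHODS)
def test_planted_feature_ranks_first(method):
    rng = np.random.default_rng(7)
    X, time, event = _survival_with_signal(rng, 300, [1.2], 19)
    opts = {"repetitions": 30} if method == "boosting" else {}
    if method == "random_forest":
        opts = {"n_trees": 100, "n_permutations": 3}
    ranking = rank_importance(X, time, event, method, seed=5, **opts)
    assert ranking.top[0] == "f00"


def test_constant_feature_importance_zero():
    rng = np.random.default_rng(3)
    X, time, event = _survival_with_signal(rng, 120, [1.0], 5)
    X["const"] = 1.0
    ranking = rank_importance(X, time, event, "lasso", seed=1)
    assert ranking.scores["const"] == 0.0


def test_intersection_semantics():
    names = [f"f{i:02d}" for i in range(16)]
    identical = [_ranking(m, names[:10]) for m in METHODS]
    assert set(intersect_top10(identical)) == set(names[:10])

    shifted = [
        _ranking("lasso", names[:10]),
        _ranking("boosting", names[4:14]),
        _ranking("random_forest", names[2:12]),
    ]
    common = intersect_top10(shifted)
    assert set(common) == set(names[4:10])  # the 6 shared features

    disjoint = [
        _ranking("lasso", [f"a{i}" for i in range(10)]),
        _ranking("boosting", [f"b{i}" for i in range(10)]),
        _ranking("random_forest", [f"c{i}" for i in range(10)]),
    ]
    with pytest.raises(SignatureError):
        intersect_top10(disjoint)


def test_breslow_loglik_matches_direct_enumeration():
    # 4 subjects, no ties: hand-expanded partial likelihood
    lp = np.array([0.5, -0.2, 1.0, 0.0])
    time = np.array([3.0, 1.0, 2.0, 4.0])
    event = np.array([True, True, False, True])
    expected = 0.0
    for i in np.where(event)[0]:
        risk = np.exp(lp[time >= time[i]]).sum()
        expected += lp[i] - np.log(risk)
    assert _breslow_partial_loglik(lp, time, event) == pytest.approx(expected)


def test_sis_arithmetic_matches_printed_weight_structure():
    # indicator weighted ln 2.04, plus a protective ln 0.41 indicator
    weights = pd.Series({"InS.TRM4.IM": np.log(2.04), "Dens.CD103.TC": np.log(0.41)})
    cutoffs = pd.Series({"InS.TRM4.IM": 1.0, "Dens.CD103.TC": 50.0})
    medians = pd.Series({"InS.TRM4.IM": 0.5, "Dens.CD103.TC": 40.0})
    feats = pd.DataFrame(
        {
            "InS.TRM4.IM": [2.0, 0.2, 2.0, np.nan],
            "Dens.CD103.TC": [10.0, 10.0, 80.0, 10.0],
        },
        index=list("wxyz"),
    )
    scored = score_patients(
        feats, list(weights.index), cutoffs, weights, 0.0, medians
    )
    assert scored.loc["w", "sis"] == pytest.approx(np.log(2.04))
    assert scored.loc["x", "sis"] == 0.0  # all indicators zero
    assert scored.loc["y", "sis"] == pytest.approx(np.log(2.04) + np.log(0.41))
    # NaN imputed to median 0.5 < cutoff -> indicator 0
    assert scored.loc["z", "sis"] == 0.0
    assert scored.loc["w", "risk_group"] == "high"
    assert scored.loc["x", "risk_group"] == "low"


def test_sis_monotone_in_positive_indicators():
    weights = pd.Series({"a": 0.7, "b": 1.1})
    cutoffs = pd.Series({"a": 0.0, "b": 0.0})
    medians = pd.Series({"a": 0.0, "b": 0.0})
    base = pd.DataFrame({"a": [-1.0], "b": [-1.0]}, index=["p"])
    up = pd.DataFrame({"a": [1.0], "b": [-1.0]}, index=["p"])
    s0 = score_patients(base, ["a", "b"], cutoffs, weights, 0.0, medians)
    s1 = score_patients(up, ["a", "b"], cutoffs, weights, 0.0, medians)
    assert s1.loc["p", "sis"] >= s0.loc["p", "sis"]


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    features, clinical = small_cohort_module
    model = SpatialSignatureModel(features, clinical)
    res = model.fit(seed=2, xgb_repetitions=25, rsf_trees=50, rsf_permutations=2)
    return model, res


@pytest.fixture(scope="module")
def small_cohort_module():
    from trm_spatial import SyntheticConfig, compute_feature_vectors, generate_cohort

    cfg = SyntheticConfig(n_patients=120, cells_per_region=250, seed=21)
    cohort, _ = generate_cohort(cfg)
    table = compute_feature_vectors(cohort)
    return table, cohort.clinical


def test_fit_is_deterministic(small_cohort_module):
    features, clinical = small_cohort_module
    kw = dict(seed=2, xgb_repetitions=25, rsf_trees=50, rsf_permutations=2)
    r1 = SpatialSignatureModel(features, clinical).fit(**kw)
    r2 = SpatialSignatureModel(features, clinical).fit(**kw)
    assert r1.selected_features == r2.selected_features
    pd.testing.assert_series_equal(r1.weights, r2.weights)
    pd.testing.assert_series_equal(r1.cutoffs, r2.cutoffs)
    assert r1.sis_cutoff == r2.sis_cutoff
    pd.testing.assert_frame_equal(r1.predict(), r2.predict())


def test_no_test_set_leakage(fitted, small_cohort_module):
    model, res = fitted
    features, clinical = small_cohort_module
    # corrupt every test-set row: the fitted model must not change
    mutated = features.df.copy()
    test_ids = res.split.test_ids
    mutated.loc[mutated.index.isin(test_ids)] = (
        mutated.loc[mutated.index.isin(test_ids)] * 13.7 + 5.0
    )
    res2 = SpatialSignatureModel(mutated, clinical).fit(
        seed=2, xgb_repetitions=25, rsf_trees=50, rsf_permutations=2
    )
    assert res2.selected_features == res.selected_features
    pd.testing.assert_series_equal(res2.weights, res.weights)
    pd.testing.assert_series_equal(res2.cutoffs, res.cutoffs)
    assert res2.sis_cutoff == res.sis_cutoff


def test_json_roundtrip_rescore(fitted, tmp_path):
    model, res = fitted
    path = tmp_path / "model.json"
    res.to_json(path)
    loaded = SignatureResults.from_json(path)
    a = res.predict(model.features)
    b = loaded.predict(model.features)
    pd.testing.assert_frame_equal(a, b)


def test_preprocessor_handles_all_missing_column():
    X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "gone": [np.nan] * 3})
    prep = Preprocessor.fit(X)
    out = prep.transform(X)
    assert np.isfinite(out.to_numpy()).all()
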