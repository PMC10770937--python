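import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from trm_spatial import (
    Cohort,
    cancer_cell_proximity_score,
    compute_feature_vectors,
    density,
    infiltration_score,
    mean_nnd,
    microvessel_correlates,
)
from trm_spatial.spatial import feature_columns, feature_name

from conftest import make_cells, make_clinical


def brute_mnnd(xy_a, xy_c):
    return float(np.mean(cdist(xy_a, xy_c).min(axis=1)))


def brute_ccps(xy_a, xy_c, r):
    if len(xy_a) == 0:
        return 0.0
    return float(np.mean((cdist(xy_c, xy_a) <= r).sum(axis=1)))


def test_density_formula_fixtures():
    rows = [("A", "TC", "stroma", i, 0, {"CD8": 1}) for i in range(5)]
    rows += [("A", "TC", "stroma", i, 5, {}) for i in range(995)]
    cells = make_cells(rows)
    assert density(cells, "CD8") == pytest.approx(5.0)
    assert density(cells, "TRM") == 0.0
    pure = make_cells([("A", "TC", "stroma", i, 0, {"CD8": 1}) for i in range(200)])
    assert density(pure, "CD8") == pytest.approx(1000.0)


def test_infiltration_score_fixtures():
    def ins_cells(n_epi, n_stro):
        rows = [("A", "TC", "epithelium", i, 0, {"CD8": 1, "CD103": 1})
                for i in range(n_epi)]
        rows += [("A", "TC", "stroma", i, 9, {"CD8": 1, "CD103": 1})
                 for i in range(n_stro)]
        rows += [("A", "TC", "stroma", 0, 50, {})]
        return make_cells(rows)

    val, flag = infiltration_score(ins_cells(10, 5), "TRM")
    assert val == pytest.approx(2.0) and flag is None
    val, flag = infiltration_score(ins_cells(0, 7), "TRM")
    assert val == 0.0 and flag is None
    val, flag = infiltration_score(ins_cells(3, 0), "TRM")
    assert np.isnan(val) and flag == "undefined-infinite"
    val, flag = infiltration_score(ins_cells(0, 0), "TRM")
    assert np.isnan(val) and flag == "empty"


def test_mnnd_three_four_five_triangle():
    a = np.array([[0.0, 0.0]])
    cancer = np.array([[3.0, 4.0], [10.0, 0.0]])
    assert mean_nnd(a, cancer) == pytest.approx(5.0)
    # coincident point contributes zero
    assert mean_nnd(np.array([[3.0, 4.0]]), cancer) == 0.0
    assert np.isnan(mean_nnd(np.empty((0, 2)), cancer))


def test_ccps_mean_count_fixture():
    cancer = np.array([[0.0, 0.0], [100.0, 0.0]])
    a = np.array([[1.0, 0.0], [0.0, 2.0], [-3.0, 0.0], [101.0, 0.0]])
    # cancer cell 1 sees 3 A cells within r=20, cancer cell 2 sees 1
    assert cancer_cell_proximity_score(a, cancer, 20.0) == pytest.approx(2.0)
    assert cancer_cell_proximity_score(np.empty((0, 2)), cancer, 20.0) == 0.0
    assert np.isnan(cancer_cell_proximity_score(a, np.empty((0, 2)), 20.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tree_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n_a, n_c = rng.integers(1, 60, size=2)
    xy_a = rng.uniform(0, 200, size=(n_a, 2))
    xy_c = rng.uniform(0, 200, size=(n_c, 2))
    r = float(rng.uniform(5, 50))
    assert mean_nnd(xy_a, xy_c) == pytest.approx(brute_mnnd(xy_a, xy_c), rel=1e-9)
    assert cancer_cell_proximity_score(xy_a, xy_c, r) == pytest.approx(
        brute_ccps(xy_a, xy_c, r), rel=1e-9
    )


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rigid_motion_invariance(seed):
    rng = np.random.default_rng(seed)
    xy_a = rng.uniform(0, 100, size=(25, 2))
    xy_c = rng.uniform(0, 100, size=(30, 2))
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = rng.uniform(-500, 500, size=2)
    ta, tc = xy_a @ rot.T + shift, xy_c @ rot.T + shift
    assert mean_nnd(ta, tc) == pytest.approx(mean_nnd(xy_a, xy_c), rel=1e-9)
    assert cancer_cell_proximity_score(ta, tc, 25.0) == pytest.approx(
        cancer_cell_proximity_score(xy_a, xy_c, 25.0), rel=1e-9
    )


def test_ccps_monotonicity(rng):
    xy_a = rng.uniform(0, 100, size=(40, 2))
    xy_c = rng.uniform(0, 100, size=(30, 2))
    radii = [5, 10, 20, 40, 80]
    scores = [cancer_cell_proximity_score(xy_a, xy_c, r) for r in radii]
    assert all(b >= a for a, b in zip(scores, scores[1:]))
    # adding an A cell never decreases CCPS
    more = np.vstack([xy_a, [[50.0, 50.0]]])
    assert cancer_cell_proximity_score(more, xy_c, 20.0) >= scores[2]


def test_density_additivity(small_cohort):
    _, cohort, _ = small_cohort
    cells = cohort.cells[
        (cohort.cells.patient_id == cohort.patient_ids[0])
        & (cohort.cells.region == "TC")
    ]
    d_trm = density(cells, "TRM")
    d_non = density(cells, "TnonRM")
    assert d_trm + d_non == pytest.approx(density(cells, "CD8"))
    subsets = sum(density(cells, s) for s in ("TRM1", "TRM2", "TRM3", "TRM4"))
    assert subsets == pytest.approx(d_trm)


def test_feature_vectors_complete_and_match_naive(small_cohort):
    _, cohort, _ = small_cohort
    table = compute_feature_vectors(cohort)
    assert list(table.df.columns) == feature_columns()
    assert len(table.df) == cohort.n_patients

    pid = cohort.patient_ids[3]
    cells = cohort.cells[
        (cohort.cells.patient_id == pid) & (cohort.cells.region == "IM")
    ]
    row = table.df.loc[pid]
    assert row[feature_name("Dens", "TRM", "IM")] == pytest.approx(
        density(cells, "TRM")
    )
    ins, _ = infiltration_score(cells, "TnonRM")
    got = row[feature_name("InS", "TnonRM", "IM")]
    assert got == pytest.approx(ins) or (np.isnan(got) and np.isnan(ins))
    from trm_spatial.phenotypes import phenotype_masks

    masks = phenotype_masks(cells)
    xy = cells[["x_um", "y_um"]].to_numpy()
    assert row[feature_name("mNND", "TRM", "IM")] == pytest.approx(
        brute_mnnd(xy[masks["TRM"]], xy[masks["CK"]]), rel=1e-9
    )
    assert row[feature_name("CCPS", "TRM", "IM")] == pytest.approx(
        brute_ccps(xy[masks["TRM"]], xy[masks["CK"]], table.radius), rel=1e-9
    )


def test_missing_region_flags_all_features(small_cohort):
    _, cohort, _ = small_cohort
    pid = cohort.patient_ids[0]
    cells_tc_only = cohort.cells[
        (cohort.cells.region == "TC") | (cohort.cells.patient_id != pid)
    ]
    table = compute_feature_vectors(
        Cohort(cells=cells_tc_only, clinical=cohort.clinical, panel="panel1")
    )
    im_cols = [c for c in table.df.columns if c.endswith(".IM")]
    assert table.df.loc[pid, im_cols].isna().all()
    assert table.flags[(pid, im_cols[0])] == "region-absent"


def test_microvessel_correlates_perfect_and_degenerate():
    # one CD31+ cell count exactly anti-monotone in TRM count -> rho = -1
    rows = []
    for i, pid in enumerate(["a", "b", "c", "d", "e"]):
        n_trm = 2 + i
        n_cd31 = 12 - i
        for region in ("TC", "IM"):
            rows += [(pid, region, "epithelium", j, 0, {"CK": 1}) for j in range(5)]
            rows += [
                (pid, region, "stroma", j, 10, {"CD8": 1, "CD103": 1})
                for j in range(n_trm)
            ]
            rows += [(pid, region, "stroma", j, 20, {"CD31": 1}) for j in range(n_cd31)]
            rows += [(pid, region, "stroma", j, 30, {}) for j in range(30 - n_trm - n_cd31)]
    cells = make_cells(rows, panel="panel2")
    cohort = Cohort(cells=cells, clinical=make_clinical(list("abcde")), panel="panel2")
    table = microvessel_correlates(cohort)
    row = table[
        (table.marker == "CD31") & (table.feature == "Dens.TRM") & (table.region == "TC")
    ].iloc[0]
    assert row.rho == pytest.approx(-1.0)
    # HIF1A density is constant 0 -> undefined ranks -> missing
    hif = table[(table.marker == "HIF1A") & (table.feature == "Dens.TRM")
                & (table.region == "TC")].iloc[0]
    assert np.isnan(hif.rho)
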