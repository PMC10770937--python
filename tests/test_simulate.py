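import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from trm_spatial import (
    SyntheticConfig,
    compute_feature_vectors,
    generate_cohort,
    generate_panel2,
    generate_patient,
    microvessel_correlates,
    read_cell_table,
    write_cell_table,
)
from trm_spatial.phenotypes import phenotype_masks
from trm_spatial.spatial import feature_name, mean_nnd


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(nest_radius_range=(400.0, 500.0), window_um=600.0).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(cd31_coupling=-1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(target_event_fraction=0.0).validate()
    SyntheticConfig().validate()


def test_seed_determinism_byte_identical(tmp_path):
    cfg = SyntheticConfig(n_patients=6, cells_per_region=150, seed=9)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(cfg)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cell_table(a.cells, p1)
    write_cell_table(b.cells, p2)
    assert p1.read_bytes() == p2.read_bytes()
    c, _ = generate_cohort(cfg, seed=10)
    assert not c.cells.equals(a.cells)


def test_generated_cells_pass_io_validation(tmp_path, small_cohort):
    _, cohort, _ = small_cohort
    path = tmp_path / "cells.csv"
    write_cell_table(cohort.cells, path)
    df = read_cell_table(path)
    assert len(df) == len(cohort.cells)


def test_marginal_frequencies_within_3_se():
    # latent coupling off so the configured rates are the exact marginals
    cfg = SyntheticConfig(
        n_patients=40, cells_per_region=500, seed=5,
        latent_sd=0.0, checkpoint_rho=0.0,
    )
    cohort, _ = generate_cohort(cfg)
    tc = cohort.cells[cohort.cells.region == "TC"]
    n = len(tc)
    for frac, col in ((cfg.frac_cancer["TC"], "CK"), (cfg.frac_cd8["TC"], "CD8")):
        # CD8 column is 1 only for CD8 cells; CK only for cancer cells
        p_hat = tc[col].mean()
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(p_hat - frac) < 3 * se
    masks = phenotype_masks(tc)
    p_cd103 = masks["TRM"].sum() / masks["CD8"].sum()
    se = np.sqrt(0.6 * 0.4 / masks["CD8"].sum())
    assert abs(p_cd103 - cfg.p_cd103_given_cd8["TC"]) < 3 * se


def test_patient_level_checkpoint_correlation_positive():
    cfg = SyntheticConfig(n_patients=80, cells_per_region=400, seed=13)
    cohort, _ = generate_cohort(cfg)
    rows = []
    for pid, cells in cohort.cells.groupby("patient_id"):
        masks = phenotype_masks(cells)
        n_cd8 = masks["CD8"].sum()
        if n_cd8 < 10:
            continue
        rows.append(
            {
                "cd103": masks["TRM"].sum() / n_cd8,
                "pd1": masks["PD1CD8"].sum() / n_cd8,
                "tim3": masks["TIM3CD8"].sum() / n_cd8,
                "gzmb": masks["GZMBCD8"].sum() / n_cd8,
            }
        )
    df = pd.DataFrame(rows)
    corr = df.corr(method="spearman")["cd103"]
    assert corr["pd1"] > 0.2 and corr["tim3"] > 0.2 and corr["gzmb"] > 0.2


def _cohort_mean_subset_mnnd(cohort, subset, region="TC"):
    vals = []
    for pid, cells in cohort.cells.groupby("patient_id"):
        sub = cells[cells.region == region]
        masks = phenotype_masks(sub)
        xy = sub[["x_um", "y_um"]].to_numpy()
        v = mean_nnd(xy[masks[subset]], xy[masks["CK"]])
        if np.isfinite(v):
            vals.append(v)
    return np.asarray(vals)


def test_graded_attraction_orders_subset_mnnd():
    cfg = SyntheticConfig(n_patients=40, cells_per_region=500, seed=17)
    cohort, _ = generate_cohort(cfg)
    m1 = _cohort_mean_subset_mnnd(cohort, "TRM1")
    m4 = _cohort_mean_subset_mnnd(cohort, "TRM4")
    assert m4.mean() < m1.mean()


def test_zero_attraction_makes_subsets_indistinguishable():
    flat = {k: 0.0 for k in ("TRM1", "TRM2", "TRM3", "TRM4", "TnonRM", "CD103only")}
    cfg = SyntheticConfig(
        n_patients=50, cells_per_region=500, seed=19, attraction=flat
    )
    cohort, _ = generate_cohort(cfg)
    m1 = _cohort_mean_subset_mnnd(cohort, "TRM1")
    m4 = _cohort_mean_subset_mnnd(cohort, "TRM4")
    assert ks_2samp(m1, m4).pvalue > 0.01


def test_event_fraction_near_target(small_cohort):
    cfg = SyntheticConfig(n_patients=274, cells_per_region=60, seed=23)
    cohort, truth = generate_cohort(cfg)
    assert abs(cohort.clinical.dfs_event.mean() - cfg.target_event_fraction) < 0.1
    assert (truth.observed_months <= truth.censoring_horizon + 1e-9).all()


def test_truth_table_matches_computed_features(small_cohort):
    cfg, cohort, truth = small_cohort
    table = compute_feature_vectors(cohort)
    merged = truth.set_index("patient_id")
    for col in cfg.planted_lnhr:
        got = table.df[col]
        expect = merged[col]
        both = got.notna() & expect.notna()
        assert np.allclose(got[both], expect[both], rtol=1e-9)
        pd.testing.assert_series_equal(
            got.isna(), expect.isna(), check_names=False
        )


def test_generate_patient_standalone(rng):
    cfg = SyntheticConfig(cells_per_region=200)
    sample = generate_patient(cfg, rng, "P7")
    assert set(sample.cells.region.unique()) == {"TC", "IM"}
    assert sample.clinical.patient_id == "P7"
    assert sample.missing_regions == ()


def test_panel2_coupling_direction():
    cfg = SyntheticConfig(n_patients=100, cells_per_region=400, seed=29)
    cohort = generate_panel2(cfg)
    table = microvessel_correlates(cohort)
    row = table[
        (table.marker == "CD31")
        & (table.feature == "Dens.TRM")
        & (table.region == "IM")
    ].iloc[0]
    assert row.rho < -0.15
    hif = table[
        (table.marker == "HIF1A")
        & (table.feature == "Dens.TRM")
        & (table.region == "IM")
    ].iloc[0]
    assert abs(hif.rho) < 0.25
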