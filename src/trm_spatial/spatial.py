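"""The four per-patient spatial immune features and their assembly.

For a phenotype A within one patient-region point pattern (planar Euclidean
coordinates in micrometres):

* ``Dens(A)``  = n(A) / n(total cells) x 1000 — density per 1000 segmented cells.
* ``InS(A)``   = n(A)^epi / n(A)^stro — epithelial-to-stromal count ratio
  (infiltration score). Undefined (missing) when the stromal count is zero
  while the epithelial count is positive.
* ``mNND(A~C)`` = mean over A cells of the Euclidean distance to the nearest
  cancer cell; lower values mean tighter contact with the tumor.
* ``CCPS(A)``  = mean over cancer cells of the number of A cells within a
  predefined radius r (cancer-cell proximity score); higher values mean more
  A cells engaging cancer cells.

Nearest-neighbour and radius queries run on a k-d tree and agree with the
O(n^2) definitions to floating-point accuracy. Distances ignore the
epithelium/stroma label and no edge correction is applied at core boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .io import REGIONS, Cohort
from .phenotypes import phenotype_masks

#: default proximity radius for CCPS, in micrometres (cell-contact scale)
DEFAULT_RADIUS_UM = 20.0

#: phenotypes whose density enters the candidate feature set
DENSITY_PHENOTYPES = (
    "CD103", "CD8", "TRM", "TnonRM",
    "TRM1", "TRM2", "TRM3", "TRM4",
    "PD1CD8", "TIM3CD8", "GZMBCD8",
)

#: phenotypes whose InS / mNND / CCPS enter the candidate feature set
SPATIAL_PHENOTYPES = ("TRM", "TnonRM", "TRM1", "TRM2", "TRM3", "TRM4")

FEATURE_KINDS = ("Dens", "InS", "mNND", "CCPS")


def feature_name(kind: str, phenotype: str, region: str) -> str:
    """Canonical feature column name, e.g. ``InS.TRM4.IM``."""
    return f"{kind}.{phenotype}.{region}"


def feature_columns() -> list[str]:
    """The full candidate feature set, in canonical order."""
    cols = []
    for region in REGIONS:
        for p in DENSITY_PHENOTYPES:
            cols.append(feature_name("Dens", p, region))
        for kind in ("InS", "mNND", "CCPS"):
            for p in SPATIAL_PHENOTYPES:
                cols.append(feature_name(kind, p, region))
    return cols


def density(cells: pd.DataFrame, phenotype: str, panel: str = "panel1") -> float:
    """Dens(A): phenotype count per 1000 total segmented cells in the region."""
    n_total = len(cells)
    if n_total == 0:
        return float("nan")
    masks = phenotype_masks(cells, panel=panel)
    return float(masks[phenotype].sum() / n_total * 1000.0)


def infiltration_score(
    cells: pd.DataFrame, phenotype: str, panel: str = "panel1"
) -> tuple[float, str | None]:
    """InS(A) = epithelial count / stromal count, with a missingness flag.

    Returns ``(value, flag)``: flag is ``None`` for a defined value,
    ``"undefined-infinite"`` when stroma count is 0 with epithelial cells
    present, and ``"empty"`` when the phenotype is absent from the region.
    """
    masks = phenotype_masks(cells, panel=panel)
    mask = masks[phenotype]
    epi = int((mask & (cells["compartment"] == "epithelium").to_numpy()).sum())
    stro = int((mask & (cells["compartment"] == "stroma").to_numpy()).sum())
    if epi == 0 and stro == 0:
        return float("nan"), "empty"
    if stro == 0:
        return float("nan"), "undefined-infinite"
    return epi / stro, None


def mean_nnd(xy_a: np.ndarray, xy_cancer: np.ndarray) -> float:
    """mNND(A~C): mean distance from each A cell to its nearest cancer cell.

    Missing (NaN) when either point set is empty.
    """
    xy_a = np.asarray(xy_a, dtype=float)
    xy_cancer = np.asarray(xy_cancer, dtype=float)
    if len(xy_a) == 0 or len(xy_cancer) == 0:
        return float("nan")
    d, _ = cKDTree(xy_cancer).query(xy_a, k=1)
    return float(np.mean(d))


def cancer_cell_proximity_score(
    xy_a: np.ndarray, xy_cancer: np.ndarray, radius: float = DEFAULT_RADIUS_UM
) -> float:
    """CCPS(A): mean number of A cells within *radius* of each cancer cell.

    Missing (NaN) when there are no cancer cells; 0.0 when there are cancer
    cells but no A cells.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xy_cancer = np.asarray(xy_cancer, dtype=float)
    if len(xy_cancer) == 0:
        return float("nan")
    xy_a = np.asarray(xy_a, dtype=float)
    if len(xy_a) == 0:
        return 0.0
    counts = cKDTree(xy_a).query_ball_point(xy_cancer, r=radius, return_length=True)
    return float(np.mean(counts))


@dataclass
class FeatureTable:
    """Per-patient feature matrix plus missing-value provenance.

    ``df`` is indexed by patient_id with one column per (kind, phenotype,
    region); missing entries are NaN and ``flags`` records why, keyed by
    ``(patient_id, column)``.
    """

    df: pd.DataFrame
    radius: float = DEFAULT_RADIUS_UM
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, radius: float = DEFAULT_RADIUS_UM) -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        df.index = df.index.astype(str)
        return cls(df=df, radius=radius)


def _region_features(
    cells: pd.DataFrame, region: str, radius: float
) -> tuple[dict[str, float], dict[str, str]]:
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    if len(cells) == 0:
        for col in feature_columns():
            if col.endswith(f".{region}"):
                values[col] = float("nan")
                flags[col] = "region-absent"
        return values, flags

    masks = phenotype_masks(cells, panel="panel1")
    n_total = len(cells)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    xy_cancer = xy[masks["CK"]]
    epi = (cells["compartment"] == "epithelium").to_numpy()
    cancer_tree = cKDTree(xy_cancer) if len(xy_cancer) else None

    for p in DENSITY_PHENOTYPES:
        values[feature_name("Dens", p, region)] = float(
            masks[p].sum() / n_total * 1000.0
        )
    for p in SPATIAL_PHENOTYPES:
        mask = masks[p]
        n_epi = int((mask & epi).sum())
        n_stro = int(mask.sum()) - n_epi
        col = feature_name("InS", p, region)
        if n_epi == 0 and n_stro == 0:
            values[col] = float("nan")
            flags[col] = "empty"
        elif n_stro == 0:
            values[col] = float("nan")
            flags[col] = "undefined-infinite"
        else:
            values[col] = n_epi / n_stro

        xy_a = xy[mask]
        col = feature_name("mNND", p, region)
        if len(xy_a) == 0 or cancer_tree is None:
            values[col] = float("nan")
            flags[col] = "no-A-cells" if cancer_tree is not None else "no-cancer-cells"
        else:
            d, _ = cancer_tree.query(xy_a, k=1)
            values[col] = float(np.mean(d))

        col = feature_name("CCPS", p, region)
        if cancer_tree is None:
            values[col] = float("nan")
            flags[col] = "no-cancer-cells"
        elif len(xy_a) == 0:
            values[col] = 0.0
        else:
            counts = cKDTree(xy_a).query_ball_point(
                xy_cancer, r=radius, return_length=True
            )
            values[col] = float(np.mean(counts))
    return values, flags


def compute_feature_vectors(
    cohort: Cohort, radius: float = DEFAULT_RADIUS_UM
) -> FeatureTable:
    """Assemble the candidate feature matrix for a panel-1 cohort.

    Per patient: Dens over :data:`DENSITY_PHENOTYPES` and InS/mNND/CCPS over
    :data:`SPATIAL_PHENOTYPES`, each in both regions. A region absent from a
    patient leaves all its features missing.
    """
    if cohort.panel != "panel1":
        raise ValueError("feature vectors are defined on panel-1 cohorts")
    rows = {}
    flags: dict[tuple[str, str], str] = {}
    grouped = dict(tuple(cohort.cells.groupby("patient_id", sort=False)))
    for pid in cohort.patient_ids:
        cells = grouped.get(pid)
        row: dict[str, float] = {}
        for region in REGIONS:
            region_cells = (
                cells[cells["region"] == region]
                if cells is not None
                else cohort.cells.iloc[0:0]
            )
            values, region_flags = _region_features(region_cells, region, radius)
            row.update(values)
            for col, why in region_flags.items():
                flags[(pid, col)] = why
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=feature_columns())
    df.index.name = "patient_id"
    df.index = df.index.astype(str)
    return FeatureTable(df=df, radius=radius, flags=flags)


def _panel2_patient_metrics(cells: pd.DataFrame, region: str, radius: float) -> dict:
    masks = phenotype_masks(cells, panel="panel2")
    n_total = len(cells)
    out: dict[str, float] = {}
    if n_total == 0:
        return {
            k: float("nan")
            for k in (
                "Dens.CD31", "Dens.HIF1A",
                "Dens.TRM", "InS.TRM", "mNND.TRM", "CCPS.TRM",
                "Dens.TnonRM", "InS.TnonRM", "mNND.TnonRM", "CCPS.TnonRM",
            )
        }
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    xy_cancer = xy[masks["CK"]]
    epi = (cells["compartment"] == "epithelium").to_numpy()
    out["Dens.CD31"] = float(masks["CD31"].sum() / n_total * 1000.0)
    out["Dens.HIF1A"] = float(masks["HIF1A"].sum() / n_total * 1000.0)
    for p in ("TRM", "TnonRM"):
        mask = masks[p]
        out[f"Dens.{p}"] = float(mask.sum() / n_total * 1000.0)
        n_epi = int((mask & epi).sum())
        n_stro = int(mask.sum()) - n_epi
        out[f"InS.{p}"] = n_epi / n_stro if n_stro > 0 else float("nan")
        out[f"mNND.{p}"] = mean_nnd(xy[mask], xy_cancer)
        out[f"CCPS.{p}"] = cancer_cell_proximity_score(xy[mask], xy_cancer, radius)
    return out


def microvessel_correlates(
    cohort: Cohort, radius: float = DEFAULT_RADIUS_UM
) -> pd.DataFrame:
    """Spearman correlations of microvessel (CD31+) and hypoxia (Hif-1a+)
    density with T_RM / T_nonRM spatial features, per region (panel 2).

    Returns a tidy frame with columns ``marker, feature, region, rho, p, n``;
    rho is missing with fewer than 3 complete pairs or a constant variable.
    """
    if cohort.panel != "panel2":
        raise ValueError("microvessel correlates require a panel-2 cohort")
    if cohort.n_patients < 3:
        raise ValueError("need at least 3 patients")
    records = []
    for region in REGIONS:
        region_cells = cohort.cells[cohort.cells["region"] == region]
        grouped = dict(tuple(region_cells.groupby("patient_id", sort=False)))
        metrics = pd.DataFrame.from_dict(
            {
                pid: _panel2_patient_metrics(
                    grouped.get(pid, region_cells.iloc[0:0]), region, radius
                )
                for pid in cohort.patient_ids
            },
            orient="index",
        )
        for marker in ("CD31", "HIF1A"):
            x = metrics[f"Dens.{marker}"]
            for p in ("TRM", "TnonRM"):
                for kind in ("Dens", "InS", "mNND", "CCPS"):
                    y = metrics[f"{kind}.{p}"]
                    ok = x.notna() & y.notna()
                    n = int(ok.sum())
                    if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                        rho, pval = float("nan"), float("nan")
                    else:
                        rho, pval = spearmanr(x[ok], y[ok])
                    records.append(
                        {
                            "marker": marker,
                            "feature": f"{kind}.{p}",
                            "region": region,
                            "rho": float(rho),
                            "p": float(pval),
                            "n": n,
                        }
                    )
    return pd.DataFrame.from_records(records)
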