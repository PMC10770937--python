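"""Domain types and table IO for multiplex-immunofluorescence cell data.

The pipeline consumes two plain CSV tables exported from upstream image
analysis: a *cell table* (one row per segmented cell, with planar coordinates
in micrometres and binary marker calls) and a *clinical table* (one row per
patient with disease-free-survival follow-up and standard covariates).
Cells are labelled with the tumor region they were sampled from (tumor
center ``TC`` or invasive margin ``IM``) and the tissue compartment the
segmenter assigned (``epithelium`` or ``stroma``).

Bulk data are held as :class:`pandas.DataFrame`; the record dataclasses
(:class:`CellRecord`, :class:`ClinicalRecord`) carry the per-record contracts
and are available for record-level work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("TC", "IM")
COMPARTMENTS = ("epithelium", "stroma")

#: marker columns per staining panel, in canonical column order
PANELS: dict[str, tuple[str, ...]] = {
    "panel1": ("CD8", "CD103", "PD1", "TIM3", "GZMB", "CK"),
    "panel2": ("CD8", "CD103", "CK", "CD31", "HIF1A"),
}

CELL_BASE_COLUMNS = ("patient_id", "region", "compartment", "x_um", "y_um")

AGE_GROUPS = ("<=60", ">60")
GENDERS = ("male", "female")
SMOKING = ("non_light", "heavy")
HISTOLOGY = ("LUAD", "LUSC")
STAGES = ("I", "II", "III")

CLINICAL_COLUMNS = (
    "patient_id",
    "age_group",
    "gender",
    "smoking",
    "histology",
    "stage",
    "dfs_months",
    "dfs_event",
)

#: coordinates are stored at 0.01 um precision
COORD_DECIMALS = 2


class FormatError(ValueError):
    """A table does not conform to the declared CSV dialect."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: location, region/compartment labels, marker calls."""

    patient_id: str
    region: str
    compartment: str
    x: float
    y: float
    markers: Mapping[str, bool]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("cell coordinates must be finite")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient covariates and disease-free-survival follow-up."""

    patient_id: str
    age_group: str
    gender: str
    smoking: str
    histology: str
    stage: str
    dfs_months: float
    dfs_event: bool

    def __post_init__(self) -> None:
        for value, levels, name in (
            (self.age_group, AGE_GROUPS, "age_group"),
            (self.gender, GENDERS, "gender"),
            (self.smoking, SMOKING, "smoking"),
            (self.histology, HISTOLOGY, "histology"),
            (self.stage, STAGES, "stage"),
        ):
            if value not in levels:
                raise ValueError(f"{name} level {value!r} not in {levels}")
        if not np.isfinite(self.dfs_months) or self.dfs_months < 0:
            raise ValueError("dfs_months must be finite and non-negative")


@dataclass
class PatientSample:
    """All cells of one patient (both regions where present) plus clinical data."""

    patient_id: str
    cells: pd.DataFrame
    clinical: ClinicalRecord

    def region_cells(self, region: str) -> pd.DataFrame:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return self.cells[self.cells["region"] == region]

    @property
    def missing_regions(self) -> tuple[str, ...]:
        present = set(self.cells["region"].unique())
        return tuple(r for r in REGIONS if r not in present)


@dataclass
class Cohort:
    """A joined cell table + clinical table for one staining panel."""

    cells: pd.DataFrame
    clinical: pd.DataFrame
    panel: str = "panel1"

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}")
        ids = self.clinical["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate patient_id in clinical table: {dupes}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def sample(self, patient_id: str) -> PatientSample:
        row = self.clinical[self.clinical["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        rec = clinical_records(row)[0]
        cells = self.cells[self.cells["patient_id"] == patient_id]
        return PatientSample(patient_id, cells, rec)

    def __iter__(self) -> Iterable[PatientSample]:
        for pid in self.patient_ids:
            yield self.sample(pid)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_cell_table(path, panel: str = "panel1") -> pd.DataFrame:
    """Read and validate a cell table CSV.

    Expected columns: ``patient_id, region, compartment, x_um, y_um`` plus one
    0/1 column per marker of *panel*. Unknown columns are ignored with a
    warning. Marker values other than 0/1 are rejected with the offending CSV
    line number (header is line 1).
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}")
    markers = PANELS[panel]
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, CELL_BASE_COLUMNS + markers, "cell table")

    known = set(CELL_BASE_COLUMNS + markers)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("cell table: ignoring unknown column(s) %s", unknown)
        df = df.drop(columns=unknown)

    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        line = int(df.index[bad_region][0]) + 2
        raise FormatError(
            f"invalid region {df.loc[bad_region, 'region'].iloc[0]!r} on line {line}"
        )
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        line = int(df.index[bad_comp][0]) + 2
        raise FormatError(
            f"invalid compartment {df.loc[bad_comp, 'compartment'].iloc[0]!r} on line {line}"
        )

    for coord in ("x_um", "y_um"):
        vals = pd.to_numeric(df[coord], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            line = int(df.index[~np.isfinite(vals.fillna(np.inf))][0]) + 2
            raise FormatError(f"non-finite {coord} on line {line}")
        df[coord] = vals.astype(float)

    for m in markers:
        vals = pd.to_numeric(df[m], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(
                f"marker {m} has non-binary value {df.loc[bad, m].iloc[0]!r} on line {line}"
            )
        df[m] = vals.astype(np.int8)

    return df.reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path, panel: str = "panel1") -> None:
    """Write a cell table; coordinates at the declared 0.01 um precision."""
    markers = PANELS[panel]
    cols = list(CELL_BASE_COLUMNS) + list(markers)
    out = cells[cols].copy()
    for coord in ("x_um", "y_um"):
        out[coord] = out[coord].round(COORD_DECIMALS)
    out.to_csv(path, index=False, float_format=f"%.{COORD_DECIMALS}f")


def cell_records(cells: pd.DataFrame, panel: str = "panel1") -> list[CellRecord]:
    """Convert a validated cell table into a list of :class:`CellRecord`."""
    markers = PANELS[panel]
    return [
        CellRecord(
            patient_id=row.patient_id,
            region=row.region,
            compartment=row.compartment,
            x=row.x_um,
            y=row.y_um,
            markers={m: bool(getattr(row, m)) for m in markers},
        )
        for row in cells.itertuples(index=False)
    ]


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate the clinical table CSV (one row per patient)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    extra = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    if extra:
        logger.warning("clinical table: ignoring unknown column(s) %s", extra)
        df = df.drop(columns=extra)

    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"].unique())
        raise FormatError(f"duplicate patient_id: {dupes}")

    for col, levels in (
        ("age_group", AGE_GROUPS),
        ("gender", GENDERS),
        ("smoking", SMOKING),
        ("histology", HISTOLOGY),
        ("stage", STAGES),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            raise FormatError(
                f"{col} level {df.loc[bad, col].iloc[0]!r} outside declared levels {levels}"
            )

    dfs = pd.to_numeric(df["dfs_months"], errors="coerce")
    if dfs.isna().any() or (dfs < 0).any():
        raise FormatError("dfs_months must be numeric and non-negative")
    df["dfs_months"] = dfs.astype(float)

    ev = pd.to_numeric(df["dfs_event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        raise FormatError("dfs_event must be 0/1")
    df["dfs_event"] = ev.astype(bool)
    return df.reset_index(drop=True)


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    out = clinical[list(CLINICAL_COLUMNS)].copy()
    out["dfs_event"] = out["dfs_event"].astype(int)
    out.to_csv(path, index=False)


def clinical_records(clinical: pd.DataFrame) -> list[ClinicalRecord]:
    return [
        ClinicalRecord(
            patient_id=row.patient_id,
            age_group=row.age_group,
            gender=row.gender,
            smoking=row.smoking,
            histology=row.histology,
            stage=row.stage,
            dfs_months=float(row.dfs_months),
            dfs_event=bool(row.dfs_event),
        )
        for row in clinical.itertuples(index=False)
    ]


def assemble_cohort(
    cells: pd.DataFrame, clinical: pd.DataFrame, panel: str = "panel1"
) -> Cohort:
    """Inner-join cell and clinical tables on patient_id into a :class:`Cohort`.

    Patients present in only one table are dropped with a logged count; an
    empty intersection is an error.
    """
    cell_ids = set(cells["patient_id"].unique())
    clin_ids = set(clinical["patient_id"].unique())
    shared = cell_ids & clin_ids
    if not shared:
        raise FormatError("cell and clinical tables share no patient_id")
    dropped = (cell_ids | clin_ids) - shared
    if dropped:
        logger.warning(
            "assemble_cohort: dropping %d patient(s) present in only one table",
            len(dropped),
        )
    cells_kept = cells[cells["patient_id"].isin(shared)].reset_index(drop=True)
    clin_kept = (
        clinical[clinical["patient_id"].isin(shared)]
        .sort_values("patient_id", kind="stable")
        .reset_index(drop=True)
    )
    return Cohort(cells=cells_kept, clinical=clin_kept, panel=panel)
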