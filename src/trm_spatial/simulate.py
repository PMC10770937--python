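"""Synthetic mIF cohort generator with planted spatial structure and survival.

Each patient contributes two regions (tumor center TC, invasive margin IM),
each a square window containing random disk-shaped epithelial nests. Cancer
cells (CK+) are placed inside nests; immune cells are placed by a mixture of
a uniform kernel and a cancer-attracted Gaussian kernel, with the attraction
weight graded across the four T_RM checkpoint subsets so that more exhausted
subsets (TRM3/TRM4) sit nearer cancer cells than TRM1/TRM2. The compartment
label of every cell is the nest mask, so the infiltration score has a
well-defined ground truth.

A per-patient latent factor tilts the CD103 fraction together with the
PD-1/Tim-3/GZMB rates, inducing the positive patient-level correlation of
CD103 with checkpoint/granzyme expression seen across real cohorts.

Disease-free survival is drawn from an exponential proportional-hazards
model whose linear predictor is built from the *realized* planted spatial
features (standardised across the cohort), plus an optional tumor-stage
effect; independent uniform censoring is calibrated to a target event
fraction. Ground truth (latent factors, realized planted features, linear
predictors, uncensored times) is returned next to the cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import yaml

from .io import COORD_DECIMALS, REGIONS, Cohort
from .phenotypes import phenotype_masks
from .spatial import (
    DEFAULT_RADIUS_UM,
    cancer_cell_proximity_score,
    mean_nnd,
)

_LN = np.log


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """All generator knobs; defaults reproduce the emulated study conditions
    (cohort size, ~39.4% event fraction, subset composition and the graded
    subset attraction)."""

    n_patients: int = 274
    seed: int = 0

    # geometry (micrometres)
    window_um: float = 600.0
    n_nests_mean: float = 4.0
    nest_radius_range: tuple[float, float] = (50.0, 110.0)

    # cells per patient-region
    cells_per_region: int = 1500
    cell_size_sd: float = 0.2  # lognormal sd of the per-patient size factor

    # phenotype frequencies per region
    frac_cancer: dict = field(default_factory=lambda: {"TC": 0.35, "IM": 0.22})
    frac_cd8: dict = field(default_factory=lambda: {"TC": 0.15, "IM": 0.18})
    p_cd103_given_cd8: dict = field(default_factory=lambda: {"TC": 0.60, "IM": 0.37})
    frac_cd103_only: dict = field(default_factory=lambda: {"TC": 0.06, "IM": 0.05})
    subset_probs: dict = field(
        default_factory=lambda: {
            "TC": (0.40, 0.10, 0.25, 0.25),
            "IM": (0.51, 0.09, 0.25, 0.15),
        }
    )
    pd1_nonrm: float = 0.15
    tim3_nonrm: float = 0.10
    gzmb_by_subset: dict = field(
        default_factory=lambda: {
            "TRM1": 0.45, "TRM2": 0.65, "TRM3": 0.40, "TRM4": 0.25
        }
    )
    gzmb_nonrm: float = 0.20

    # patient-level latent coupling (logit-scale tilts)
    latent_sd: float = 0.5
    checkpoint_rho: float = 0.5

    # spatial placement: attraction probability toward cancer cells
    attraction: dict = field(
        default_factory=lambda: {
            "TRM1": 0.15, "TRM2": 0.30, "TRM3": 0.50, "TRM4": 0.65,
            "TnonRM": 0.10, "CD103only": 0.10,
        }
    )
    attraction_sigma_um: float = 20.0

    # survival model
    planted_lnhr: dict = field(
        default_factory=lambda: {
            "InS.TnonRM.TC": _LN(0.41),
            "InS.TRM1.IM": _LN(0.36),
        }
    )
    stage_lnhr: dict = field(
        default_factory=lambda: {"II": _LN(1.63), "III": _LN(3.21)}
    )
    baseline_median_months: float = 60.0
    target_event_fraction: float = 0.394

    # clinical covariate frequencies
    p_age_over60: float = 0.50
    p_female: float = 0.35
    p_heavy_smoker: float = 0.45
    p_lusc: float = 0.347
    stage_probs: tuple[float, float, float] = (0.553, 0.200, 0.247)

    # feature radius carried to downstream defaults
    radius_um: float = DEFAULT_RADIUS_UM

    # panel 2
    cd31_coupling: float = -0.4
    frac_cd31: float = 0.05
    cd31_dispersion: float = 1.0  # log-sd of the per-patient CD31 rate
    frac_hif1a: float = 0.08
    trm_attraction_panel2: float = 0.45

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.nest_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nest radii must be positive and ordered")
        if hi * 2 > self.window_um:
            raise ValueError("epithelial nests exceed the window")
        for d in (self.frac_cancer, self.frac_cd8, self.p_cd103_given_cd8,
                  self.frac_cd103_only):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("frequencies must lie in [0, 1]")
        for probs in self.subset_probs.values():
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("subset probabilities must be length 4, sum 1")
        for v in self.attraction.values():
            if not 0 <= v <= 1:
                raise ValueError("attraction probabilities must lie in [0, 1]")
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must lie in (0, 1)")
        if abs(self.cd31_coupling) > 1:
            raise ValueError("|cd31_coupling| must be <= 1")
        for beta in {**self.planted_lnhr, **self.stage_lnhr}.values():
            if not np.isfinite(beta):
                raise ValueError("hazard parameters must be finite")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("nest_radius_range", "stage_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "subset_probs" in raw:
            raw["subset_probs"] = {
                k: tuple(v) for k, v in raw["subset_probs"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _nests(config: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    k = max(1, int(rng.poisson(config.n_nests_mean)))
    lo, hi = config.nest_radius_range
    radii = rng.uniform(lo, hi, size=k)
    centers = np.column_stack(
        [
            rng.uniform(radii, config.window_um - radii),
            rng.uniform(radii, config.window_um - radii),
        ]
    )
    return centers, radii


def _in_nest(xy: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    if len(xy) == 0:
        return np.zeros(0, dtype=bool)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= (radii ** 2)[None, :]).any(axis=1)


def _uniform_in_nests(n: int, centers: np.ndarray, radii: np.ndarray, rng) -> np.ndarray:
    weights = radii ** 2 / (radii ** 2).sum()
    idx = rng.choice(len(radii), size=n, p=weights)
    ang = rng.uniform(0, 2 * np.pi, size=n)
    rad = radii[idx] * np.sqrt(rng.uniform(0, 1, size=n))
    return centers[idx] + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def _attracted_positions(
    n: int, attract_p: float, xy_cancer: np.ndarray, config: SyntheticConfig, rng
) -> np.ndarray:
    """Mixture of uniform placement and a Gaussian kernel around cancer cells."""
    W = config.window_um
    xy = rng.uniform(0, W, size=(n, 2))
    if len(xy_cancer) and attract_p > 0:
        near = rng.uniform(0, 1, size=n) < attract_p
        k = int(near.sum())
        if k:
            anchors = xy_cancer[rng.integers(0, len(xy_cancer), size=k)]
            jitter = rng.normal(0, config.attraction_sigma_um, size=(k, 2))
            xy[near] = np.clip(anchors + jitter, 0, W)
    return xy


def _region_cells(
    config: SyntheticConfig, rng, patient_id: str, region: str, u: float, n_cells: int,
    panel: str,
) -> dict[str, np.ndarray]:
    centers, radii = _nests(config, rng)
    tilt = config.latent_sd * u
    p_cancer = config.frac_cancer[region]
    p_cd8 = config.frac_cd8[region]
    p_cd103_cd8 = _expit(_logit(config.p_cd103_given_cd8[region]) + tilt)
    p_cd103_only = _expit(_logit(config.frac_cd103_only[region]) + tilt)

    kinds = rng.choice(
        4,
        size=n_cells,
        p=[
            p_cancer,
            p_cd8,
            p_cd103_only * (1 - p_cancer - p_cd8),
            (1 - p_cd103_only) * (1 - p_cancer - p_cd8),
        ],
    )
    n_cancer = int((kinds == 0).sum())
    n_cd8 = int((kinds == 1).sum())
    n_cd103only = int((kinds == 2).sum())
    n_other = n_cells - n_cancer - n_cd8 - n_cd103only

    xy_cancer = _uniform_in_nests(n_cancer, centers, radii, rng)

    # CD8 cells: CD103 call, subset, GZMB, then subset-specific placement
    cd103 = rng.uniform(0, 1, size=n_cd8) < p_cd103_cd8
    subset = np.zeros(n_cd8, dtype=int)  # 1..4 for TRM subsets, 0 for TnonRM
    base = np.asarray(config.subset_probs[region], dtype=float)
    rho = config.checkpoint_rho * u
    # odds tilt: checkpoint-positive subsets up-weighted with the latent factor
    tilts = np.exp(rho * np.array([0.0, 1.0, 1.0, 2.0]))
    probs = base * tilts
    probs /= probs.sum()
    subset[cd103] = rng.choice(4, size=int(cd103.sum()), p=probs) + 1

    pd1 = np.zeros(n_cd8, dtype=bool)
    tim3 = np.zeros(n_cd8, dtype=bool)
    gzmb = np.zeros(n_cd8, dtype=bool)
    pd1[np.isin(subset, (2, 4))] = True
    tim3[np.isin(subset, (3, 4))] = True
    nonrm = subset == 0
    pd1[nonrm] = rng.uniform(0, 1, size=int(nonrm.sum())) < _expit(
        _logit(config.pd1_nonrm) + rho
    )
    tim3[nonrm & ~pd1] = rng.uniform(0, 1, size=int((nonrm & ~pd1).sum())) < _expit(
        _logit(config.tim3_nonrm) + rho
    )
    subset_names = {1: "TRM1", 2: "TRM2", 3: "TRM3", 4: "TRM4"}
    for s, name in subset_names.items():
        m = subset == s
        gzmb[m] = rng.uniform(0, 1, size=int(m.sum())) < _expit(
            _logit(config.gzmb_by_subset[name]) + rho
        )
    gzmb[nonrm] = rng.uniform(0, 1, size=int(nonrm.sum())) < _expit(
        _logit(config.gzmb_nonrm) + rho
    )

    xy_cd8 = np.zeros((n_cd8, 2))
    if panel == "panel1":
        attract = {0: config.attraction["TnonRM"]}
        attract.update(
            {s: config.attraction[name] for s, name in subset_names.items()}
        )
    else:
        attract = {0: config.attraction["TnonRM"]}
        attract.update({s: config.trm_attraction_panel2 for s in subset_names})
    for s, a in attract.items():
        m = subset == s
        if m.any():
            xy_cd8[m] = _attracted_positions(int(m.sum()), a, xy_cancer, config, rng)

    xy_cd103only = _attracted_positions(
        n_cd103only, config.attraction["CD103only"], xy_cancer, config, rng
    )
    xy_other = rng.uniform(0, config.window_um, size=(n_other, 2))

    xy = np.vstack([xy_cancer, xy_cd8, xy_cd103only, xy_other]).round(COORD_DECIMALS)
    n = len(xy)
    cols: dict[str, np.ndarray] = {
        "patient_id": np.repeat(patient_id, n),
        "region": np.repeat(region, n),
        "compartment": np.where(_in_nest(xy, centers, radii), "epithelium", "stroma"),
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "CD8": np.concatenate(
            [np.zeros(n_cancer), np.ones(n_cd8), np.zeros(n_cd103only + n_other)]
        ).astype(np.int8),
        "CD103": np.concatenate(
            [np.zeros(n_cancer), cd103, np.ones(n_cd103only), np.zeros(n_other)]
        ).astype(np.int8),
        "CK": np.concatenate(
            [np.ones(n_cancer), np.zeros(n - n_cancer)]
        ).astype(np.int8),
    }
    if panel == "panel1":
        cols["PD1"] = np.concatenate(
            [np.zeros(n_cancer), pd1, np.zeros(n_cd103only + n_other)]
        ).astype(np.int8)
        cols["TIM3"] = np.concatenate(
            [np.zeros(n_cancer), tim3, np.zeros(n_cd103only + n_other)]
        ).astype(np.int8)
        cols["GZMB"] = np.concatenate(
            [np.zeros(n_cancer), gzmb, np.zeros(n_cd103only + n_other)]
        ).astype(np.int8)
    else:
        # CD31/HIF1A are assigned cohort-wide in generate_panel2 (the CD31
        # rate couples to the realized T_RM density across patients)
        cols["CD31"] = np.zeros(n, dtype=np.int8)
        cols["HIF1A"] = np.zeros(n, dtype=np.int8)
    return cols


def _draw_clinical(config: SyntheticConfig, rng, patient_id: str) -> dict:
    stage = ("I", "II", "III")[rng.choice(3, p=list(config.stage_probs))]
    return {
        "patient_id": patient_id,
        "age_group": ">60" if rng.uniform() < config.p_age_over60 else "<=60",
        "gender": "female" if rng.uniform() < config.p_female else "male",
        "smoking": "heavy" if rng.uniform() < config.p_heavy_smoker else "non_light",
        "histology": "LUSC" if rng.uniform() < config.p_lusc else "LUAD",
        "stage": stage,
    }


def _patient_frames(
    config: SyntheticConfig, rng, patient_id: str, panel: str
) -> tuple[pd.DataFrame, float]:
    u = float(rng.normal())
    frames = []
    size_factor = float(np.exp(rng.normal(0, config.cell_size_sd)))
    for region in REGIONS:
        n_cells = max(20, int(rng.poisson(config.cells_per_region * size_factor)))
        frames.append(
            pd.DataFrame(_region_cells(config, rng, patient_id, region, u, n_cells, panel))
        )
    return pd.concat(frames, ignore_index=True), u


def generate_patient(config: SyntheticConfig, rng, patient_id: str = "P0"):
    """One patient's two-region point pattern plus clinical covariates.

    Survival here reflects the baseline hazard only; cohort-level generation
    replaces it with the feature-based proportional-hazards draw.
    """
    from .io import PatientSample, clinical_records

    config.validate()
    cells, _ = _patient_frames(config, rng, patient_id, "panel1")
    clin = _draw_clinical(config, rng, patient_id)
    lam = np.log(2) / config.baseline_median_months
    t = float(rng.exponential(1.0 / lam))
    clin.update(dfs_months=round(t, 2), dfs_event=True)
    rec = clinical_records(pd.DataFrame([clin]))[0]
    return PatientSample(patient_id, cells, rec)


def draw_survival_times(
    linear_predictor: np.ndarray,
    rng,
    baseline_median_months: float = 60.0,
    target_event_fraction: float = 0.394,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Exponential PH event times plus independent uniform censoring.

    The censoring horizon ``c_max`` is calibrated so the expected event
    fraction over the realized event times equals the target; returns
    (observed time, event indicator, uncensored time, c_max).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    lam0 = np.log(2) / baseline_median_months
    t_true = rng.exponential(1.0, size=len(lp)) / (lam0 * np.exp(lp))

    def expected_events(c_max: float) -> float:
        return float(np.mean(np.clip(1.0 - t_true / c_max, 0.0, 1.0)))

    lo, hi = 1e-6, 1e7
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected_events(mid) < target_event_fraction:
            lo = mid
        else:
            hi = mid
    c_max = np.sqrt(lo * hi)
    censor = rng.uniform(0, c_max, size=len(lp))
    observed = np.minimum(t_true, censor)
    event = t_true <= censor
    return observed, event, t_true, float(c_max)


def _planted_feature_values(
    cells: pd.DataFrame, patient_ids, names: list[str], radius: float
) -> pd.DataFrame:
    """Realized values of the planted features only (cheap targeted pass)."""
    out = {name: [] for name in names}
    grouped = dict(tuple(cells.groupby(["patient_id", "region"], sort=False)))
    for pid in patient_ids:
        for name in names:
            kind, phen, region = name.split(".")
            sub = grouped.get((pid, region))
            if sub is None or len(sub) == 0:
                out[name].append(np.nan)
                continue
            masks = phenotype_masks(sub, panel="panel1")
            xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
            mask = masks[phen]
            if kind == "Dens":
                out[name].append(mask.sum() / len(sub) * 1000.0)
            elif kind == "InS":
                epi = (sub["compartment"] == "epithelium").to_numpy()
                n_epi = int((mask & epi).sum())
                n_stro = int(mask.sum()) - n_epi
                out[name].append(n_epi / n_stro if n_stro > 0 else np.nan)
            elif kind == "mNND":
                out[name].append(mean_nnd(xy[mask], xy[masks["CK"]]))
            elif kind == "CCPS":
                out[name].append(
                    cancer_cell_proximity_score(xy[mask], xy[masks["CK"]], radius)
                )
            else:
                raise ValueError(f"unknown feature kind in {name!r}")
    return pd.DataFrame(out, index=pd.Index(patient_ids, name="patient_id"))


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Full panel-1 cohort plus the ground-truth table.

    Survival is generated from the realized planted features (standardised
    across the cohort, cohort-median imputation for the rare undefined value)
    and the configured stage effect, so recovery targets are exactly what the
    pipeline measures downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pids = [f"P{i:04d}" for i in range(config.n_patients)]
    cell_frames, latents, clin_rows = [], [], []
    for pid in pids:
        cells, u = _patient_frames(config, rng, pid, "panel1")
        cell_frames.append(cells)
        latents.append(u)
        clin_rows.append(_draw_clinical(config, rng, pid))
    cells = pd.concat(cell_frames, ignore_index=True)
    clinical = pd.DataFrame(clin_rows)

    planted = list(config.planted_lnhr)
    truth = pd.DataFrame({"latent_u": latents}, index=pd.Index(pids, name="patient_id"))
    lp = np.zeros(config.n_patients)
    if planted:
        feats = _planted_feature_values(cells, pids, planted, config.radius_um)
        for name in planted:
            vals = feats[name].to_numpy(dtype=float)
            filled = np.where(np.isnan(vals), np.nanmedian(vals), vals)
            sd = filled.std()
            z = (filled - filled.mean()) / (sd if sd > 0 else 1.0)
            lp += config.planted_lnhr[name] * z
            truth[name] = vals
    for stage_level, beta in config.stage_lnhr.items():
        lp += beta * (clinical["stage"] == stage_level).to_numpy(dtype=float)
    # centre so the configured baseline median describes the average patient
    # and the calibrated follow-up spans the 1/3/5-year horizons
    lp -= lp.mean()
    truth["linear_predictor"] = lp

    observed, event, t_true, c_max = draw_survival_times(
        lp, rng, config.baseline_median_months, config.target_event_fraction
    )
    truth["true_time_months"] = t_true
    truth["observed_months"] = np.round(observed, 2)
    truth["event"] = event
    truth["censoring_horizon"] = c_max

    clinical["dfs_months"] = np.round(observed, 2)
    clinical["dfs_event"] = event
    cohort = Cohort(cells=cells, clinical=clinical, panel="panel1")
    return cohort, truth.reset_index()


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal scores (ties share the mean rank)."""
    from scipy.stats import norm, rankdata

    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def generate_panel2(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Panel-2 cohort (CD8/CD103/CK/CD31/HIF1A).

    The per-region CD31+ rate follows a Gaussian copula against the *realized*
    T_RM density across patients at the configured (negative) coupling, so the
    measured Spearman correlation tracks the knob up to CD31 counting noise
    alone; the Hif-1a+ rate is drawn independently of T_RM.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pids = [f"V{i:04d}" for i in range(config.n_patients)]
    cell_frames, clin_rows = [], []
    for pid in pids:
        cells, _ = _patient_frames(config, rng, pid, "panel2")
        cell_frames.append(cells)
        clin = _draw_clinical(config, rng, pid)
        lam = np.log(2) / config.baseline_median_months
        clin.update(
            dfs_months=round(float(rng.exponential(1.0 / lam)), 2), dfs_event=True
        )
        clin_rows.append(clin)
    cells = pd.concat(cell_frames, ignore_index=True)

    rho = config.cd31_coupling
    for region in REGIONS:
        in_region = (cells["region"] == region).to_numpy()
        trm = ((cells["CD8"] == 1) & (cells["CD103"] == 1)).to_numpy()
        dens = np.array(
            [
                trm[in_region & (cells["patient_id"] == pid).to_numpy()].mean()
                for pid in pids
            ]
        )
        z = _normal_scores(dens)
        eps = rng.normal(size=len(pids))
        v = rho * z + np.sqrt(1.0 - rho ** 2) * eps
        w = rng.normal(size=len(pids))
        unlabelled = (
            in_region
            & (cells["CD8"] == 0)
            & (cells["CD103"] == 0)
            & (cells["CK"] == 0)
        )
        hif_eligible = in_region & (cells["CD8"] == 0) & (cells["CD103"] == 0)
        for i, pid in enumerate(pids):
            pmask = (cells["patient_id"] == pid).to_numpy()
            p31 = min(
                config.frac_cd31 * float(np.exp(config.cd31_dispersion * v[i])), 0.5
            )
            phif = min(
                config.frac_hif1a * float(np.exp(config.cd31_dispersion * w[i])), 0.5
            )
            idx = np.flatnonzero(unlabelled & pmask)
            cells.loc[idx[rng.uniform(size=len(idx)) < p31], "CD31"] = 1
            hdx = np.flatnonzero(hif_eligible & pmask)
            cells.loc[hdx[rng.uniform(size=len(hdx)) < phif], "HIF1A"] = 1
    return Cohort(cells=cells, clinical=pd.DataFrame(clin_rows), panel="panel2")
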