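"""Survival evaluation: Kaplan-Meier/log-rank, Cox models with backward
elimination, time-dependent ROC, and the SIS+stage combined model.

Disease-free survival (DFS) is measured in months from surgery to progression
or last follow-up. Hazard ratios come from proportional-hazards fits with
explicit reference levels; the time-dependent AUC is the cumulative-case /
dynamic-control variant with inverse-probability-of-censoring weighting
(IPCW), evaluated at fixed horizons (12/36/60 months by default). Two-sided
alpha = 0.05 throughout, with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

DEFAULT_HORIZONS = (12, 36, 60)

#: declared level order (first = reference) for categorical covariates
CANONICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<=60", ">60"),
    "gender": ("male", "female"),
    "smoking": ("non_light", "heavy"),
    "histology": ("LUAD", "LUSC"),
    "stage": ("I", "II", "III"),
    "sis_group": ("low", "high"),
    "risk_group": ("low", "high"),
}


@dataclass
class KMResult:
    """Kaplan-Meier curves per group with the log-rank test."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    n: dict[str, int]
    events: dict[str, int]
    p: float
    statistic: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=label)
        ax.set_xlabel("months")
        ax.set_ylabel("DFS probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def km_logrank(groups, time, event) -> KMResult:
    """Kaplan-Meier estimates and the log-rank test across >= 2 groups.

    Median DFS is NaN (not reached) when the curve never drops below 0.5;
    with no events at all the test p-value is missing.
    """
    groups = pd.Series(np.asarray(groups, dtype=object), name="group")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("log-rank comparison needs at least 2 groups")
    curves, medians, n, events = {}, {}, {}, {}
    for label in labels:
        mask = (groups == label).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        med = kmf.median_survival_time_
        medians[label] = float(med) if np.isfinite(med) else float("nan")
        n[label] = int(mask.sum())
        events[label] = int(event[mask].sum())
    if event.sum() == 0:
        p, stat = float("nan"), float("nan")
    else:
        res = multivariate_logrank_test(time, groups.to_numpy(), event)
        p, stat = float(res.p_value), float(res.test_statistic)
    return KMResult(curves=curves, medians=medians, n=n, events=events,
                    p=p, statistic=stat)


def _design(df: pd.DataFrame, covariate: str) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Dummy-code one covariate against its declared reference level.

    Returns the design columns and (covariate, level) labels; numeric
    covariates pass through as a single column labelled with an empty level.
    """
    col = df[covariate]
    if pd.api.types.is_numeric_dtype(col) and covariate not in CANONICAL_LEVELS:
        return pd.DataFrame({covariate: col.astype(float)}), [(covariate, "")]
    levels = CANONICAL_LEVELS.get(covariate)
    observed = list(pd.unique(col.astype(str)))
    if levels is None:
        levels = tuple(sorted(observed))
    present = [l for l in levels if l in observed]
    if len(present) < 2:
        raise ValueError(f"covariate {covariate} has fewer than 2 observed levels")
    design = {}
    labels = []
    for level in present[1:]:
        name = f"{covariate}[{level}]"
        design[name] = (col.astype(str) == level).astype(float)
        labels.append((covariate, level))
    return pd.DataFrame(design, index=df.index), labels


def _fit_cox(df: pd.DataFrame, design: pd.DataFrame, labels, duration_col, event_col):
    data = design.copy()
    data["T"] = df[duration_col].astype(float)
    data["E"] = df[event_col].astype(int)
    cph = CoxPHFitter()
    cph.fit(data, duration_col="T", event_col="E")
    rows = []
    for (cov, level), name in zip(labels, design.columns):
        rows.append(
            {
                "variable": cov,
                "level": level,
                "hr": float(np.exp(cph.params_[name])),
                "ci_lower": float(np.exp(cph.confidence_intervals_.loc[name].iloc[0])),
                "ci_upper": float(np.exp(cph.confidence_intervals_.loc[name].iloc[1])),
                "p": float(cph.summary.loc[name, "p"]),
            }
        )
    return pd.DataFrame(rows), cph


@dataclass
class CoxModelResults:
    """Univariate and backward-eliminated multivariate Cox fits (Table-1 style)."""

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    retained: list[str]
    failed: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Cox proportional-hazards models (DFS)", "=" * 54, "univariate:"]
        for _, r in self.univariate.iterrows():
            lines.append(
                f"  {r['variable']:<12}{r['level']:<10}"
                f"HR {r['hr']:.2f} ({r['ci_lower']:.2f}, {r['ci_upper']:.2f})"
                f"  p={r['p']:.3g}"
            )
        lines.append(f"multivariate (retained: {', '.join(self.retained) or 'none'}):")
        for _, r in self.multivariate.iterrows():
            lines.append(
                f"  {r['variable']:<12}{r['level']:<10}"
                f"HR {r['hr']:.2f} ({r['ci_lower']:.2f}, {r['ci_upper']:.2f})"
                f"  p={r['p']:.3g}"
            )
        for cov, msg in self.failed.items():
            lines.append(f"  {cov}: fit failed ({msg})")
        return "\n".join(lines)


def cox_models(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "dfs_months",
    event_col: str = "dfs_event",
    alpha: float = 0.05,
) -> CoxModelResults:
    """Univariate Cox per covariate, then multivariate with backward elimination.

    The multivariate model starts from covariates with any univariate p <
    *alpha* and iteratively removes the covariate whose best level p is
    largest until every remaining covariate has a level below *alpha*.
    """
    if int(df[event_col].sum()) < 10:
        raise ValueError("Cox modelling needs at least 10 events")
    uni_rows = []
    failed: dict[str, str] = {}
    uni_p: dict[str, float] = {}
    for cov in covariates:
        try:
            design, labels = _design(df, cov)
            table, _ = _fit_cox(df, design, labels, duration_col, event_col)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            failed[cov] = str(exc)
            continue
        uni_rows.append(table)
        uni_p[cov] = float(table["p"].min())
    univariate = (
        pd.concat(uni_rows, ignore_index=True) if uni_rows else pd.DataFrame()
    )

    current = [c for c, p in uni_p.items() if p < alpha]
    multivariate = pd.DataFrame(
        columns=["variable", "level", "hr", "ci_lower", "ci_upper", "p"]
    )
    while current:
        designs, labels = [], []
        for cov in current:
            d, l = _design(df, cov)
            designs.append(d)
            labels.extend(l)
        design = pd.concat(designs, axis=1)
        try:
            table, _ = _fit_cox(df, design, labels, duration_col, event_col)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            failed["+".join(current)] = str(exc)
            break
        worst_cov, worst_p = None, -1.0
        for cov in current:
            p = float(table.loc[table["variable"] == cov, "p"].min())
            if p > worst_p:
                worst_cov, worst_p = cov, p
        if worst_p < alpha:
            multivariate = table
            break
        current = [c for c in current if c != worst_cov]
        if not current:
            break
    return CoxModelResults(
        univariate=univariate,
        multivariate=multivariate,
        retained=current,
        failed=failed,
    )


def time_dependent_auc(
    score,
    time,
    event,
    horizons=DEFAULT_HORIZONS,
    train_time=None,
    train_event=None,
) -> pd.DataFrame:
    """Cumulative/dynamic time-dependent AUC with IPCW at fixed horizons.

    The censoring distribution is estimated on ``train_*`` (defaults to the
    scored sample itself). Horizons with no observed case, or beyond the
    follow-up range, yield a missing AUC.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if train_time is None:
        train_time, train_event = time, event
    train_time = np.asarray(train_time, dtype=float)
    train_event = np.asarray(train_event, dtype=bool)
    y_train = Surv.from_arrays(event=train_event, time=train_time)
    y_test = Surv.from_arrays(event=event, time=time)
    rows = []
    for h in horizons:
        n_cases = int((event & (time <= h)).sum())
        auc = float("nan")
        if n_cases > 0 and h < time.max():
            try:
                aucs, _ = cumulative_dynamic_auc(y_train, y_test, score, [h])
                auc = float(aucs[0])
            except ValueError:
                auc = float("nan")
        rows.append({"horizon": h, "auc": auc, "n_cases": n_cases})
    return pd.DataFrame(rows)


@dataclass
class CombinedModelResult:
    """SIS+stage combined risk model with per-model AUCs."""

    aucs: pd.DataFrame
    linear_predictor: pd.Series

    def summary(self) -> str:
        wide = self.aucs.pivot(index="model", columns="horizon", values="auc")
        return "time-dependent AUC by model\n" + wide.round(3).to_string()


def combined_model(
    df: pd.DataFrame,
    horizons=DEFAULT_HORIZONS,
    sis_col: str = "sis_group",
    stage_col: str = "stage",
    duration_col: str = "dfs_months",
    event_col: str = "dfs_event",
) -> CombinedModelResult:
    """Proportional-hazards risk score over {SIS group, stage}, with AUCs of
    the combined, stage-only and SIS-only models at each horizon."""
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=bool)
    rows = []
    lp_combined = None
    for model_name, covs in (
        ("combined", [sis_col, stage_col]),
        ("stage_only", [stage_col]),
        ("sis_only", [sis_col]),
    ):
        designs, labels = [], []
        for cov in covs:
            d, l = _design(df, cov)
            designs.append(d)
            labels.extend(l)
        design = pd.concat(designs, axis=1)
        _, cph = _fit_cox(df, design, labels, duration_col, event_col)
        data = design.copy()
        lp = cph.predict_log_partial_hazard(data)
        if model_name == "combined":
            lp_combined = pd.Series(np.asarray(lp, dtype=float), index=df.index)
        auc_df = time_dependent_auc(np.asarray(lp, dtype=float), time, event, horizons)
        for _, r in auc_df.iterrows():
            rows.append(
                {"model": model_name, "horizon": int(r["horizon"]), "auc": r["auc"]}
            )
    return CombinedModelResult(
        aucs=pd.DataFrame(rows), linear_predictor=lp_combined
    )


@dataclass
class SurvivalEvaluation:
    """Signature evaluation across train / test / entire cohort."""

    scores: pd.DataFrame
    km: dict[str, KMResult | None]
    aucs: pd.DataFrame
    cox: CoxModelResults | None

    def summary(self) -> str:
        lines = ["Signature survival evaluation", "=" * 54]
        for subset, res in self.km.items():
            if res is None:
                lines.append(f"{subset}: KM comparison not available")
                continue
            meds = ", ".join(
                f"{g}: {('%.1f' % m) if np.isfinite(m) else 'not reached'}"
                for g, m in res.medians.items()
            )
            lines.append(f"{subset}: log-rank p={res.p:.3g}; median DFS {meds}")
        wide = self.aucs.pivot(index="set", columns="horizon", values="auc")
        lines.append("time-dependent AUC (continuous SIS):")
        lines.append(wide.round(3).to_string())
        if self.cox is not None:
            lines.append(self.cox.summary())
        return "\n".join(lines)


def evaluate_signature(results, horizons=DEFAULT_HORIZONS) -> SurvivalEvaluation:
    """Evaluate a fitted :class:`~trm_spatial.signature.SignatureResults`.

    KM/log-rank of high vs low SIS and IPCW AUCs of the continuous SIS per
    train/test/entire subset, plus Table-1-style Cox models on the entire
    cohort (clinical covariates + SIS group). The censoring distribution for
    the AUC is always estimated on the training subset.
    """
    scored = results.scores_by_set()
    clinical = results.model.clinical.loc[scored.index]
    df = scored.join(clinical[["dfs_months", "dfs_event", "age_group", "gender",
                               "smoking", "histology", "stage"]])
    train = df[df["set"] == "train"]
    km: dict[str, KMResult | None] = {}
    auc_rows = []
    for subset in ("train", "test", "entire"):
        sub = df if subset == "entire" else df[df["set"] == subset]
        if sub["risk_group"].nunique() >= 2 and sub["dfs_event"].sum() > 0:
            km[subset] = km_logrank(
                sub["risk_group"], sub["dfs_months"], sub["dfs_event"]
            )
        else:
            km[subset] = None
        auc_df = time_dependent_auc(
            sub["sis"],
            sub["dfs_months"],
            sub["dfs_event"],
            horizons,
            train_time=train["dfs_months"],
            train_event=train["dfs_event"],
        )
        for _, r in auc_df.iterrows():
            auc_rows.append(
                {"set": subset, "horizon": int(r["horizon"]), "auc": r["auc"]}
            )
    df_entire = df.rename(columns={"risk_group": "sis_group"})
    try:
        cox = cox_models(
            df_entire,
            ["age_group", "gender", "smoking", "histology", "stage", "sis_group"],
        )
    except ValueError:
        cox = None
    return SurvivalEvaluation(
        scores=scored, km=km, aucs=pd.DataFrame(auc_rows), cox=cox
    )
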