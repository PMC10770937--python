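"""Construction of the T_RM-based spatial immune signature (T_RM-SIS).

The signature is built on a 7:3 train/test split of the cohort:

1. candidate per-patient spatial features are median-imputed and
   standardised on the training set;
2. three survival learners rank feature importance — an L1-penalised Cox
   model (penalty by ten-fold cross-validation), gradient-boosted Cox trees
   (gain importance averaged over bootstrap repetitions), and a random
   survival forest (permutation importance);
3. the intersection of their top-10 lists gives the selected features;
4. each selected feature is dichotomised at its maximally selected log-rank
   cut-point and weighted by the log hazard ratio of a univariate Cox fit of
   disease-free survival on the indicator (training set only):

       SIS = sum_i ln(HR_i) * X_i,   X_i = 1[feature_i > cutoff_i]

5. patients are split into high/low risk at the SIS's own cut-point.

Everything a scored patient touches — imputation medians, cut-points,
weights and the SIS threshold — derives from training data only.

The public surface is statsmodels-like: :class:`SpatialSignatureModel`
holds the data, ``fit`` returns a :class:`SignatureResults` carrying
estimates, diagnostics, ``predict``/``summary``/``evaluate`` and JSON
round-trip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import KFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .cutpoint import CutpointError, find_cutoff
from .io import Cohort
from .spatial import DEFAULT_RADIUS_UM, FeatureTable, compute_feature_vectors

logger = logging.getLogger(__name__)

METHODS = ("lasso", "boosting", "random_forest")


class SignatureError(RuntimeError):
    """Signature construction failed (e.g. empty top-k intersection)."""


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible train/test assignment at a fixed ratio."""

    seed: int
    test_fraction: float
    assignment: dict[str, str]

    @property
    def train_ids(self) -> list[str]:
        return [p for p, s in self.assignment.items() if s == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [p for p, s in self.assignment.items() if s == "test"]


def split_cohort(
    clinical: pd.DataFrame,
    seed: int,
    test_fraction: float = 0.3,
    n_candidate_features: int | None = None,
) -> SplitSpec:
    """Random 7:3 (by default) train/test split of patients.

    Reports the events-per-variable (EPV) ratio in the training set and warns
    below the conventional floor of 10 events per candidate variable.
    """
    ids = list(clinical["patient_id"])
    if len(ids) < 20:
        raise ValueError("need at least 20 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round((1.0 - test_fraction) * len(ids)))
    train_set = {ids[i] for i in order[:n_train]}
    assignment = {pid: ("train" if pid in train_set else "test") for pid in ids}
    if n_candidate_features:
        events = int(
            clinical.loc[clinical["patient_id"].isin(train_set), "dfs_event"].sum()
        )
        epv = events / n_candidate_features
        if epv < 10:
            warnings.warn(
                f"training set has {epv:.1f} events per candidate variable (<10 EPV)"
            )
    return SplitSpec(seed=seed, test_fraction=test_fraction, assignment=assignment)


@dataclass
class Preprocessor:
    """Median imputation + standardisation, fitted on training data only."""

    medians: pd.Series
    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Preprocessor":
        medians = X.median()
        # an all-missing column has no median; fall back to 0 so the column
        # survives as a constant (importance 0)
        medians = medians.fillna(0.0)
        imputed = X.fillna(medians)
        stds = imputed.std(ddof=0)
        return cls(medians=medians, means=imputed.mean(), stds=stds)

    def impute(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.fillna(self.medians)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        imputed = self.impute(X)
        safe_std = self.stds.replace(0.0, 1.0)
        return (imputed - self.means) / safe_std


def _breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of linear predictors on a sample."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # running log-sum-exp of the risk set (times descending)
    loglik = 0.0
    log_risk = -np.inf
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        block = lp[i:j]
        m = max(log_risk, block.max())
        log_risk = m + np.log(np.exp(log_risk - m) + np.exp(block - m).sum())
        for k in range(i, j):
            if event[k]:
                loglik += lp[k] - log_risk
        i = j
    return float(loglik)


@dataclass
class ImportanceRanking:
    """One learner's feature-importance scores and its top-k list."""

    method: str
    scores: pd.Series
    top: list[str]

    @classmethod
    def from_scores(cls, method: str, scores: pd.Series, k: int) -> "ImportanceRanking":
        ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
        return cls(method=method, scores=scores, top=list(ordered.index[:k]))

    def rank_of(self, feature: str) -> int:
        ordered = self.scores.sort_index().sort_values(ascending=False, kind="stable")
        return int(np.flatnonzero(ordered.index == feature)[0]) + 1


def _lasso_importance(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray, seed: int, n_folds: int
) -> pd.Series:
    y = Surv.from_arrays(event=event, time=time)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=50, alpha_min_ratio=0.05, fit_baseline_model=False
    )
    Xv = X.to_numpy(dtype=float)
    path.fit(Xv, y)
    alphas = np.asarray(path.alphas_)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_scores = np.zeros(len(alphas))
    cv_counts = np.zeros(len(alphas))
    for tr, te in kf.split(Xv):
        if event[te].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        try:
            m.fit(Xv[tr], y[tr])
        except (ValueError, ArithmeticError):  # pragma: no cover - degenerate fold
            continue
        fitted = np.asarray(m.alphas_)
        for ai, a in enumerate(alphas):
            if not np.any(np.isclose(fitted, a)):
                continue
            lp = m.predict(Xv[te], alpha=a)
            cv_scores[ai] += _breslow_partial_loglik(lp, time[te], event[te])
            cv_counts[ai] += 1
    valid = cv_counts > 0
    if not valid.any():  # pragma: no cover - pathological inputs
        raise SignatureError("penalised Cox cross-validation failed on every fold")
    mean_scores = np.where(valid, cv_scores / np.maximum(cv_counts, 1), -np.inf)
    best = int(np.argmax(mean_scores))
    coefs = pd.DataFrame(path.coef_, index=X.columns, columns=range(len(alphas)))
    return coefs[best].abs()


def _boosting_importance(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    seed: int,
    repetitions: int,
    rounds: int,
) -> pd.Series:
    import xgboost as xgb

    label = np.where(event, time, -time)
    rng = np.random.default_rng(seed)
    total = pd.Series(0.0, index=X.columns)
    Xv = X.to_numpy(dtype=float)
    names = [c.replace("[", "(").replace("]", ")") for c in X.columns]
    params = {
        "objective": "survival:cox",
        "eta": 0.1,
        "max_depth": 2,
        "subsample": 0.8,
        "lambda": 1.0,
        "nthread": 1,
        "verbosity": 0,
    }
    n = len(label)
    for rep in range(repetitions):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            continue
        dtrain = xgb.DMatrix(Xv[idx], label=label[idx], feature_names=names)
        booster = xgb.train(
            {**params, "seed": int(rng.integers(0, 2**31 - 1))},
            dtrain,
            num_boost_round=rounds,
        )
        gains = booster.get_score(importance_type="total_gain")
        for name, gain in gains.items():
            total.iloc[names.index(name)] += gain
    return total / max(repetitions, 1)


def _forest_importance(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    seed: int,
    n_trees: int,
    n_permutations: int,
) -> pd.Series:
    y = Surv.from_arrays(event=event, time=time)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=15,
        max_features="sqrt",
        n_jobs=1,
        random_state=seed,
    )
    Xv = X.to_numpy(dtype=float)
    rsf.fit(Xv, y)
    baseline = concordance_index_censored(event, time, rsf.predict(Xv))[0]
    rng = np.random.default_rng(seed)
    importance = pd.Series(0.0, index=X.columns)
    for j, col in enumerate(X.columns):
        drop = 0.0
        for _ in range(n_permutations):
            Xp = Xv.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drop += baseline - concordance_index_censored(
                event, time, rsf.predict(Xp)
            )[0]
        importance[col] = drop / n_permutations
    return importance


def rank_importance(
    X: pd.DataFrame,
    time,
    event,
    method: str,
    seed: int,
    top_k: int = 10,
    **options,
) -> ImportanceRanking:
    """Rank candidate features by one survival learner's importance.

    *X* must already be median-imputed and standardised (training statistics).
    Methods: ``lasso`` (|coefficient| at the CV-selected penalty), ``boosting``
    (mean total gain over bootstrap refits of a gradient-boosted Cox model),
    ``random_forest`` (permutation drop in concordance of a random survival
    forest). Ties are broken by lexicographic feature name. Constant features
    receive importance 0.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    constant = X.nunique() <= 1
    if constant.any():
        logger.info("constant feature(s) get importance 0: %s",
                    list(X.columns[constant]))
    Xw = X.loc[:, ~constant]
    if method == "lasso":
        scores = _lasso_importance(
            Xw, time, event, seed, n_folds=options.get("n_folds", 10)
        )
    elif method == "boosting":
        scores = _boosting_importance(
            Xw, time, event, seed,
            repetitions=options.get("repetitions", 1000),
            rounds=options.get("rounds", 50),
        )
    else:
        scores = _forest_importance(
            Xw, time, event, seed,
            n_trees=options.get("n_trees", 200),
            n_permutations=options.get("n_permutations", 3),
        )
    scores = scores.reindex(X.columns).fillna(0.0)
    return ImportanceRanking.from_scores(method, scores, top_k)


def intersect_top10(rankings: list[ImportanceRanking]) -> list[str]:
    """Features common to all three top-k lists, ordered by mean rank."""
    if len(rankings) != 3:
        raise ValueError("expected exactly 3 rankings")
    common = set(rankings[0].top)
    for r in rankings[1:]:
        common &= set(r.top)
    if not common:
        raise SignatureError(
            "top-k lists of the three learners share no feature; "
            "consider a larger top-k or more data"
        )
    mean_rank = {f: np.mean([r.rank_of(f) for r in rankings]) for f in common}
    return sorted(common, key=lambda f: (mean_rank[f], f))


def _univariate_lnhr(
    indicator: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    df = pd.DataFrame({"x": indicator.astype(float), "T": time, "E": event.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    coef = float(cph.params_["x"])
    if not np.isfinite(coef):
        raise ConvergenceError("non-finite coefficient")
    return coef


def score_patients(
    features: pd.DataFrame,
    selected_features: list[str],
    cutoffs: pd.Series,
    weights: pd.Series,
    sis_cutoff: float,
    medians: pd.Series,
) -> pd.DataFrame:
    """SIS = sum_i ln(HR_i) * X_i and the high/low risk group per patient.

    Missing feature values are imputed with the training medians before
    dichotomisation; a patient is high risk iff SIS > ``sis_cutoff``.
    """
    X = features[selected_features].fillna(medians[selected_features])
    indicators = (X > cutoffs[selected_features]).astype(float)
    sis = indicators @ weights[selected_features]
    out = pd.DataFrame(
        {
            "sis": sis.astype(float),
            "risk_group": np.where(sis > sis_cutoff, "high", "low"),
        },
        index=features.index,
    )
    out.index.name = "patient_id"
    return out


class SpatialSignatureModel:
    """T_RM spatial-immune-signature model over per-patient features + DFS.

    Parameters
    ----------
    features : FeatureTable or DataFrame
        Per-patient candidate features (rows indexed by patient_id).
    clinical : DataFrame
        Validated clinical table with ``dfs_months`` / ``dfs_event``.
    """

    def __init__(self, features, clinical: pd.DataFrame, radius: float | None = None):
        if isinstance(features, FeatureTable):
            if radius is None:
                radius = features.radius
            features = features.df
        self.radius = DEFAULT_RADIUS_UM if radius is None else radius
        clinical = clinical.set_index("patient_id", drop=False)
        clinical.index = clinical.index.astype(str)
        shared = features.index.intersection(clinical.index)
        if len(shared) == 0:
            raise ValueError("features and clinical tables share no patient")
        self.features = features.loc[shared]
        self.clinical = clinical.loc[shared]
        self.time = self.clinical["dfs_months"].to_numpy(dtype=float)
        self.event = self.clinical["dfs_event"].to_numpy(dtype=bool)

    @classmethod
    def from_cohort(cls, cohort: Cohort, radius: float = DEFAULT_RADIUS_UM):
        table = compute_feature_vectors(cohort, radius=radius)
        return cls(table, cohort.clinical, radius=radius)

    def fit(
        self,
        seed: int = 0,
        test_fraction: float = 0.3,
        top_k: int = 10,
        min_group_fraction: float = 0.1,
        lasso_folds: int = 10,
        xgb_repetitions: int = 1000,
        xgb_rounds: int = 50,
        rsf_trees: int = 200,
        rsf_permutations: int = 3,
    ) -> "SignatureResults":
        """Run the full signature construction on a fresh 7:3 split."""
        split = split_cohort(
            self.clinical,
            seed=seed,
            test_fraction=test_fraction,
            n_candidate_features=self.features.shape[1],
        )
        train_ids = [p for p in self.features.index if split.assignment[p] == "train"]
        X_train = self.features.loc[train_ids]
        clin_train = self.clinical.loc[train_ids]
        t_train = clin_train["dfs_months"].to_numpy(dtype=float)
        e_train = clin_train["dfs_event"].to_numpy(dtype=bool)

        prep = Preprocessor.fit(X_train)
        X_std = prep.transform(X_train)

        method_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                        for s in np.random.SeedSequence(seed).spawn(3)]
        rankings = [
            rank_importance(X_std, t_train, e_train, "lasso",
                            method_seeds[0], top_k, n_folds=lasso_folds),
            rank_importance(X_std, t_train, e_train, "boosting",
                            method_seeds[1], top_k,
                            repetitions=xgb_repetitions, rounds=xgb_rounds),
            rank_importance(X_std, t_train, e_train, "random_forest",
                            method_seeds[2], top_k,
                            n_trees=rsf_trees, n_permutations=rsf_permutations),
        ]
        selected = intersect_top10(rankings)

        X_imp = prep.impute(X_train)
        cutoffs: dict[str, float] = {}
        weights: dict[str, float] = {}
        dropped: list[str] = []
        for feat in selected:
            vals = X_imp[feat].to_numpy(dtype=float)
            try:
                cut = find_cutoff(vals, t_train, e_train,
                                  min_fraction=min_group_fraction)
                weights[feat] = _univariate_lnhr(vals > cut, t_train, e_train)
                cutoffs[feat] = cut
            except (CutpointError, ConvergenceError) as exc:
                warnings.warn(f"dropping feature {feat}: {exc}")
                dropped.append(feat)
        kept = [f for f in selected if f not in dropped]
        if not kept:
            raise SignatureError("no selected feature survived cut-point/Cox fitting")

        cutoffs_s = pd.Series(cutoffs)[kept]
        weights_s = pd.Series(weights)[kept]
        indicators = (X_imp[kept] > cutoffs_s).astype(float)
        sis_train = indicators @ weights_s
        try:
            sis_cutoff = find_cutoff(
                sis_train.to_numpy(), t_train, e_train,
                min_fraction=min_group_fraction,
            )
            sis_cutoff_method = "max-logrank"
        except CutpointError:
            sis_cutoff = float(np.median(sis_train))
            sis_cutoff_method = "median-fallback"
            warnings.warn("SIS cut-point search infeasible; using training median")

        return SignatureResults(
            model=self,
            split=split,
            preprocessor=prep,
            rankings={r.method: r for r in rankings},
            selected_features=kept,
            dropped_features=dropped,
            cutoffs=cutoffs_s,
            weights=weights_s,
            sis_cutoff=float(sis_cutoff),
            sis_cutoff_method=sis_cutoff_method,
            seed=seed,
        )


@dataclass
class SignatureResults:
    """Fitted T_RM-SIS: selected features, cut-points, ln(HR) weights and the
    high/low threshold — everything needed to re-score any cohort."""

    selected_features: list[str]
    cutoffs: pd.Series
    weights: pd.Series
    sis_cutoff: float
    sis_cutoff_method: str
    seed: int
    preprocessor: Preprocessor
    split: SplitSpec | None = None
    rankings: dict[str, ImportanceRanking] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)
    model: "SpatialSignatureModel | None" = None

    def predict(self, features: pd.DataFrame | None = None) -> pd.DataFrame:
        """Score patients: SIS value and high/low risk group."""
        if features is None:
            if self.model is None:
                raise ValueError("no features given and no model attached")
            features = self.model.features
        if isinstance(features, FeatureTable):
            features = features.df
        return score_patients(
            features,
            self.selected_features,
            self.cutoffs,
            self.weights,
            self.sis_cutoff,
            self.preprocessor.medians,
        )

    def scores_by_set(self) -> pd.DataFrame:
        """Scores for the fitting cohort with the train/test assignment."""
        if self.model is None or self.split is None:
            raise ValueError("results are detached from a fitted model")
        scored = self.predict()
        scored["set"] = [self.split.assignment[p] for p in scored.index]
        return scored

    def summary(self) -> str:
        lines = ["T_RM spatial immune signature", "=" * 46]
        if self.split is not None:
            lines.append(
                f"split: {len(self.split.train_ids)} train / "
                f"{len(self.split.test_ids)} test (seed {self.seed})"
            )
        lines.append(f"selected features ({len(self.selected_features)}):")
        lines.append(f"{'feature':<18}{'cutoff':>10}{'ln(HR)':>10}{'HR':>8}")
        for f in self.selected_features:
            w = self.weights[f]
            lines.append(
                f"{f:<18}{self.cutoffs[f]:>10.4g}{w:>10.3f}{np.exp(w):>8.2f}"
            )
        if self.dropped_features:
            lines.append(f"dropped: {', '.join(self.dropped_features)}")
        lines.append(
            f"SIS cut-point: {self.sis_cutoff:.4f} ({self.sis_cutoff_method})"
        )
        return "\n".join(lines)

    def evaluate(self, horizons=(12, 36, 60)):
        """Survival evaluation of the fitted signature (KM/log-rank,
        Cox models, time-dependent AUC) on train, test and entire cohort."""
        from .survival import evaluate_signature

        return evaluate_signature(self, horizons=horizons)

    def to_json(self, path=None) -> str:
        payload = {
            "selected_features": self.selected_features,
            "cutoffs": {k: float(v) for k, v in self.cutoffs.items()},
            "weights": {k: float(v) for k, v in self.weights.items()},
            "sis_cutoff": self.sis_cutoff,
            "sis_cutoff_method": self.sis_cutoff_method,
            "seed": self.seed,
            "radius_um": self.model.radius if self.model is not None else None,
            "train_medians": {
                k: float(v) for k, v in self.preprocessor.medians.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SignatureResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        medians = pd.Series(payload["train_medians"], dtype=float)
        prep = Preprocessor(
            medians=medians,
            means=medians * 0.0,
            stds=medians * 0.0 + 1.0,
        )
        return cls(
            selected_features=list(payload["selected_features"]),
            cutoffs=pd.Series(payload["cutoffs"], dtype=float),
            weights=pd.Series(payload["weights"], dtype=float),
            sis_cutoff=float(payload["sis_cutoff"]),
            sis_cutoff_method=payload.get("sis_cutoff_method", "max-logrank"),
            seed=int(payload.get("seed", 0)),
            preprocessor=prep,
        )
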