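"""Kidney-function analysis: CKD-EPI eGFR, Spearman association screens,
and cross-validated random-forest importance for eGFR.

The random forest follows the out-of-bag permutation-importance convention
(%IncMSE): each feature's contribution is the mean increase in a tree's
out-of-bag MSE when that feature's values are shuffled.  Feature- and
model-level significance come from response-permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "PatientRecord",
    "AssociationMatrix",
    "RFReport",
    "ckd_epi_egfr",
    "spearman_association",
    "rf_egfr",
]

UMOL_PER_MGDL = 88.42

# CKD-EPI creatinine coefficients: sex -> (kappa, alpha)
_CKD_EPI = {
    2021: {
        "prefactor": 142.0,
        "age_base": 0.9938,
        "max_exp": -1.200,
        "female_factor": 1.012,
        "female": (0.7, -0.241),
        "male": (0.9, -0.302),
    },
    2009: {
        "prefactor": 141.0,
        "age_base": 0.993,
        "max_exp": -1.209,
        "female_factor": 1.018,
        "female": (0.7, -0.329),
        "male": (0.9, -0.411),
    },
}


@dataclass
class PatientRecord:
    """Minimal record for eGFR: creatinine must carry an explicit unit."""

    sample_id: str
    age: float
    sex: str
    serum_creatinine: float
    creatinine_unit: str  # "mg/dL" or "umol/L"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age or self.age <= 0:
            raise ValueError("age must be positive")
        if not self.serum_creatinine or self.serum_creatinine <= 0:
            raise ValueError("serum creatinine must be positive")
        if self.creatinine_unit not in ("mg/dL", "umol/L"):
            raise ValueError(
                "creatinine unit must be given explicitly as 'mg/dL' or 'umol/L' "
                f"(got {self.creatinine_unit!r}); refusing to guess"
            )

    def creatinine_mgdl(self) -> float:
        if self.creatinine_unit == "mg/dL":
            return self.serum_creatinine
        return self.serum_creatinine / UMOL_PER_MGDL


@dataclass
class AssociationMatrix:
    """Feature x indicator Spearman correlations with significance stars."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample counts


@dataclass
class RFReport:
    """Cross-validated random-forest regression report for eGFR."""

    best_max_features: int
    cv_rmse: float
    cv_r2: float
    oob_r2: float
    importance: pd.Series  # mean increase in OOB MSE per feature
    importance_p: pd.Series | None
    model_p: float | None
    n_trees: int
    n_folds: int
    n_samples: int
    seed: int


def ckd_epi_egfr(record: PatientRecord, version: int = 2021) -> float:
    """CKD-EPI creatinine eGFR in mL/min/1.73 m^2.

    Default is the 2021 race-free refit:
    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age
    (* 1.012 if female), with k = 0.7/0.9 and a = -0.241/-0.302 for
    female/male.  ``version=2009`` gives the original coefficients with the
    race term omitted.  Piecewise-continuous at Scr = k and monotone
    decreasing in creatinine.
    """
    if version not in _CKD_EPI:
        raise ValueError(f"version must be one of {sorted(_CKD_EPI)}, got {version}")
    c = _CKD_EPI[version]
    kappa, alpha = c[record.sex]
    scr = record.creatinine_mgdl()
    ratio = scr / kappa
    egfr = (
        c["prefactor"]
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** c["max_exp"]
        * c["age_base"] ** record.age
    )
    if record.sex == "female":
        egfr *= c["female_factor"]
    return float(egfr)


def _star(p: float, tiers=(0.05, 0.01, 0.001)) -> str:
    if np.isnan(p):
        return ""
    if p < tiers[2]:
        return "***"
    if p < tiers[1]:
        return "**"
    if p < tiers[0]:
        return "*"
    return ""


def spearman_association(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    tiers: tuple = (0.05, 0.01, 0.001),
) -> AssociationMatrix:
    """Spearman rho of every feature against every clinical indicator.

    Both inputs are samples x columns; only shared samples are used and
    missing values are handled pairwise-complete.  Pairs with fewer than 5
    complete observations or a constant margin report NaN.
    """
    shared = features.index.intersection(clinical.index)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    f = features.loc[shared]
    c = clinical.loc[shared]
    rho = pd.DataFrame(index=f.columns, columns=c.columns, dtype=float)
    pmat = pd.DataFrame(index=f.columns, columns=c.columns, dtype=float)
    nmat = pd.DataFrame(index=f.columns, columns=c.columns, dtype=float)
    for feat in f.columns:
        for ind in c.columns:
            pair = pd.concat([f[feat], c[ind]], axis=1).dropna()
            nmat.loc[feat, ind] = len(pair)
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if len(pair) < 5 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rho.loc[feat, ind] = np.nan
                pmat.loc[feat, ind] = np.nan
                continue
            r, p = spearmanr(x, y)
            rho.loc[feat, ind] = r
            pmat.loc[feat, ind] = p
    stars = pmat.map(lambda p: _star(p, tiers))
    return AssociationMatrix(rho=rho, p=pmat, stars=stars, n=nmat)


def _build_forest(max_features: int, n_trees: int, seed: int) -> BaggingRegressor:
    # a bagged ensemble of feature-subsampling trees == random forest, with
    # public access to each tree's bootstrap indices (estimators_samples_)
    return BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=max_features, random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _oob_importance(
    forest: BaggingRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Per-feature mean increase in OOB MSE, and the OOB R^2 of the forest."""
    n, p = X.shape
    deltas = np.zeros(p)
    n_trees = len(forest.estimators_)
    oob_pred_sum = np.zeros(n)
    oob_pred_count = np.zeros(n)
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sample_idx, assume_unique=False)
        if oob.size < 2:
            continue
        x_oob = X[oob]
        pred = tree.predict(x_oob)
        mse0 = float(np.mean((y[oob] - pred) ** 2))
        oob_pred_sum[oob] += pred
        oob_pred_count[oob] += 1
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(oob.size), j]
            mse_j = float(np.mean((y[oob] - tree.predict(x_perm)) ** 2))
            deltas[j] += mse_j - mse0
    deltas /= n_trees
    covered = oob_pred_count > 0
    oob_pred = oob_pred_sum[covered] / oob_pred_count[covered]
    y_cov = y[covered]
    ss_res = float(((y_cov - oob_pred) ** 2).sum())
    ss_tot = float(((y_cov - y_cov.mean()) ** 2).sum())
    oob_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return deltas, oob_r2


def rf_egfr(
    features: pd.DataFrame,
    egfr: pd.Series,
    n_folds: int = 10,
    n_trees: int = 500,
    n_importance_perms: int = 100,
    seed: int = 0,
    max_features_grid: list | None = None,
) -> RFReport:
    """Random-forest prediction of eGFR with OOB permutation importance.

    The per-split candidate-feature count is grid-tuned by k-fold
    cross-validation minimising RMSE; the winner is refit on all data.
    Importance is the mean increase in out-of-bag MSE under per-feature
    shuffling; per-feature and model-level p-values come from refitting on
    ``n_importance_perms`` response permutations (set 0 to skip).  Fully
    deterministic for a given seed.
    """
    shared = features.index.intersection(egfr.index)
    data = features.loc[shared].join(egfr.loc[shared].rename("__y__")).dropna()
    X = data.drop(columns="__y__").to_numpy(float)
    y = data["__y__"].to_numpy(float)
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} complete samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    ss = np.random.SeedSequence(seed)
    cv_seed, fit_seed, imp_seed, perm_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    )
    if max_features_grid is None:
        max_features_grid = sorted(
            {1, max(1, round(np.sqrt(p))), max(1, p // 3), max(1, p // 2), p}
        )
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
    folds = list(kf.split(X))
    cv_stats = {}
    for m in max_features_grid:
        preds = np.empty(n)
        for train, test in folds:
            forest = _build_forest(m, n_trees, fit_seed)
            forest.fit(X[train], y[train])
            preds[test] = forest.predict(X[test])
        rmse = float(np.sqrt(np.mean((y - preds) ** 2)))
        r2 = 1.0 - float(((y - preds) ** 2).sum() / ((y - y.mean()) ** 2).sum())
        cv_stats[m] = (rmse, r2)
    best = min(cv_stats, key=lambda m: (cv_stats[m][0], m))
    cv_rmse, cv_r2 = cv_stats[best]
    forest = _build_forest(best, n_trees, fit_seed)
    forest.fit(X, y)
    rng = np.random.default_rng(imp_seed)
    importance, oob_r2 = _oob_importance(forest, X, y, rng)
    importance_p = None
    model_p = None
    if n_importance_perms > 0:
        perm_rng = np.random.default_rng(perm_seed)
        exceed = np.zeros(p)
        r2_exceed = 0
        for b in range(n_importance_perms):
            y_b = perm_rng.permutation(y)
            forest_b = _build_forest(best, n_trees, fit_seed + 1 + b)
            forest_b.fit(X, y_b)
            imp_b, r2_b = _oob_importance(
                forest_b, X, y_b, np.random.default_rng(imp_seed + 1 + b)
            )
            exceed += imp_b >= importance
            if r2_b >= oob_r2:
                r2_exceed += 1
        importance_p = pd.Series(
            (1.0 + exceed) / (1.0 + n_importance_perms), index=data.columns.drop("__y__")
        )
        model_p = float((1.0 + r2_exceed) / (1.0 + n_importance_perms))
    return RFReport(
        best_max_features=int(best),
        cv_rmse=cv_rmse,
        cv_r2=cv_r2,
        oob_r2=float(oob_r2),
        importance=pd.Series(importance, index=data.columns.drop("__y__")),
        importance_p=importance_p,
        model_p=model_p,
        n_trees=n_trees,
        n_folds=n_folds,
        n_samples=n,
        seed=seed,
    )
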