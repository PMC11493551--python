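"""Model evaluation: goodness of fit, cross-validated prediction, diagnostics.

McFadden's R² (1 − ℓ/ℓ₀), stratified 10-fold cross-validation with
accuracy/precision/recall/F1 and a rank-based (Mann–Whitney, ties counted
half) AUC, nested-model deviance ANOVA (χ² primary, F alongside), binned
residual summaries, Tukey HSD across factor groups, and compilation of any
per-window metric into a 365-day time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .glm import FittedModel, WindowSeries, fit_bglm, resolve_formula

logger = logging.getLogger(__name__)


def mcfadden_r2(model: FittedModel) -> float:
    """McFadden's pseudo-R²: improvement of the fit over the intercept-only
    model, ``1 − ℓ_model / ℓ_null`` ∈ [0, 1)."""
    if model.degenerate:
        raise ValueError(f"model is degenerate ({model.reason})")
    if model.llnull == 0:
        raise ValueError("null log-likelihood is zero (all-equal outcome); "
                         "McFadden's R² is undefined")
    return 1.0 - model.llf / model.llnull


def rank_auc(y_true, scores) -> float:
    """AUC via the rank (Mann–Whitney U) formulation; ties count half."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes")
    ranks = stats.rankdata(s)  # average ranks over ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy/precision/recall/F1 from a pooled confusion matrix."""
    y = np.asarray(y_true)
    p = np.asarray(y_pred)
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    accuracy = (tp + tn) / max(len(y), 1)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "accuracy": accuracy,
            "precision": precision, "recall": recall, "f1": f1}


@dataclass
class CvReport:
    k: int
    seed: int
    threshold: float
    per_fold: pd.DataFrame
    pooled: dict

    def metric(self, name: str) -> float:
        return float(self.pooled[name])


def cross_validate(table: pd.DataFrame, formula: str = "bglm3", k: int = 10,
                   seed: int = 0, threshold: float = 0.5,
                   max_refolds: int = 5) -> CvReport:
    """Seeded stratified k-fold cross-validation of a binomial GLM.

    Each fold is held out once, the model refitted on the remainder, and the
    held-out predictions scored.  A fold whose training part loses an outcome
    class triggers a refold with a fresh seed (logged).
    """
    formula = resolve_formula(formula)
    y_all = table["established"].to_numpy()
    if len(table) < k:
        raise ValueError(f"need at least k={k} rows")
    if len(np.unique(y_all)) < 2:
        raise ValueError("both outcome classes must be present")

    for attempt in range(max_refolds):
        folds = list(StratifiedKFold(n_splits=k, shuffle=True,
                                     random_state=seed + attempt)
                     .split(np.zeros(len(table)), y_all))
        if all(len(np.unique(y_all[tr])) == 2 for tr, _ in folds):
            if attempt:
                logger.info("refolded %d time(s) to keep both classes "
                            "in every training part", attempt)
            break
    else:
        raise ValueError("could not build folds with both classes present")

    fold_rows = []
    pooled_y, pooled_pred, pooled_score = [], [], []
    for i, (tr, te) in enumerate(folds):
        model = fit_bglm(table.iloc[tr], formula)
        if model.degenerate:
            raise ValueError(f"fold {i} training fit degenerate: {model.reason}")
        from .glm import predict_ep
        scores = predict_ep(model, table.iloc[te])["ep"].to_numpy()
        y_te = y_all[te]
        pred = (scores >= threshold).astype(int)
        m = confusion_metrics(y_te, pred)
        m["fold"] = i
        m["auc"] = (rank_auc(y_te, scores)
                    if len(np.unique(y_te)) == 2 else np.nan)
        fold_rows.append(m)
        pooled_y.append(y_te)
        pooled_pred.append(pred)
        pooled_score.append(scores)

    y = np.concatenate(pooled_y)
    pred = np.concatenate(pooled_pred)
    score = np.concatenate(pooled_score)
    pooled = confusion_metrics(y, pred)
    pooled["auc"] = rank_auc(y, score)
    return CvReport(k=k, seed=seed, threshold=threshold,
                    per_fold=pd.DataFrame(fold_rows), pooled=pooled)


def anova_nested(model_small: FittedModel, model_big: FittedModel) -> dict:
    """Deviance ANOVA between two nested binomial GLMs on the same data.

    Reports the deviance change with its df, the χ² p-value (primary for a
    binomial family) and the F statistic with its p-value alongside.
    """
    for m in (model_small, model_big):
        if m.degenerate:
            raise ValueError(f"degenerate model ({m.reason})")
    if model_small.nobs != model_big.nobs:
        raise ValueError("models were fitted on different numbers of rows")
    small_terms = set(model_small.term_names)
    big_terms = set(model_big.term_names)
    if not small_terms <= big_terms:
        raise ValueError(f"models are not nested: {sorted(small_terms - big_terms)} "
                         "missing from the larger model")
    d_df = model_small.df_resid - model_big.df_resid
    d_dev = model_small.deviance - model_big.deviance
    if d_df <= 0:
        p_chi = 1.0 if abs(d_dev) < 1e-8 else np.nan
        return {"df": d_df, "deviance": d_dev, "p_chisq": p_chi,
                "F": np.nan, "p_F": p_chi}
    p_chi = float(stats.chi2.sf(d_dev, d_df))
    f_stat = (d_dev / d_df) / (model_big.deviance / model_big.df_resid)
    p_f = float(stats.f.sf(f_stat, d_df, model_big.df_resid))
    return {"df": d_df, "deviance": d_dev, "p_chisq": p_chi,
            "F": float(f_stat), "p_F": p_f}


@dataclass
class BinnedResiduals:
    """Per-bin residual summaries (bins partition rows by fitted value)."""

    table: pd.DataFrame  # columns: mean_fitted, mean_residual, band, n

    @property
    def n_bins(self):
        return len(self.table)

    def fraction_within_band(self) -> float:
        t = self.table
        return float((np.abs(t["mean_residual"]) <= t["band"]).mean())


def binned_residuals(model: FittedModel, n_bins: int | None = None) -> BinnedResiduals:
    """Sort rows by fitted probability, cut into near-equal bins (default
    ⌊√n⌋) and summarise each bin's mean residual with a ±2·SE band."""
    if model.degenerate or model.fitted is None:
        raise ValueError("model has no fitted values")
    fitted = np.asarray(model.fitted)
    resid = np.asarray(model.observed) - fitted
    n = len(fitted)
    if n_bins is None:
        n_bins = max(int(np.floor(np.sqrt(n))), 1)
    if n_bins > n:
        raise ValueError(f"n_bins ({n_bins}) exceeds number of rows ({n})")
    order = np.argsort(fitted, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        r = resid[chunk]
        band = 2.0 * r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.inf
        rows.append({"mean_fitted": float(fitted[chunk].mean()),
                     "mean_residual": float(r.mean()),
                     "band": float(band), "n": int(len(chunk))})
    return BinnedResiduals(table=pd.DataFrame(rows))


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group-mean differences with studentised-range-adjusted
    intervals and p-values.  Singleton groups are excluded (logged)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    singletons = labels[counts < 2]
    if singletons.size:
        logger.info("excluding singleton groups from Tukey HSD: %s",
                    list(singletons))
        keep = ~np.isin(groups, singletons)
        values, groups = values[keep], groups[keep]
        labels = labels[counts >= 2]
    if len(labels) < 2:
        raise ValueError("need at least two groups with n >= 2")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    from itertools import combinations
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame({
        "group1": [str(a) for a, _ in pairs],
        "group2": [str(b) for _, b in pairs],
        "meandiff": res.meandiffs,
        "lower": res.confint[:, 0],
        "upper": res.confint[:, 1],
        "p_adj": res.pvalues,
        "reject": res.reject,
    })


def establishment_groups(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Default Tukey grouping: replicate outcomes by SE × PN combination."""
    labels = (table["SE"].astype(str) + ":PN" + table["PN"].astype(str)).to_numpy()
    return table["established"].to_numpy(float), labels


_MODEL_METRICS = {
    "mcfadden": lambda m: mcfadden_r2(m),
    "residual_deviance": lambda m: m.deviance,
    "null_deviance": lambda m: m.null_deviance,
    "ssr": lambda m: float(np.sum((m.observed - m.fitted) ** 2)),
    "loglik": lambda m: m.llf,
}


def compile_series(series: WindowSeries, metric="mcfadden") -> pd.DataFrame:
    """Compile one value per window into a day-of-year time series.

    ``metric`` is a name from {mcfadden, residual_deviance, null_deviance,
    ssr, loglik}, a coefficient name (e.g. ``Intercept``), or a callable
    taking a :class:`FittedModel`.  Degenerate windows carry NaN and a flag.
    """
    if callable(metric):
        fn = metric
    elif metric in _MODEL_METRICS:
        fn = _MODEL_METRICS[metric]
    else:
        term = metric

        def fn(m):
            if term not in m.params.index:
                raise KeyError(f"no term {term!r} in model")
            return float(m.params[term])
    rows = []
    for e in series.entries:
        if e.degenerate or e.model is None:
            rows.append({"day_of_year": e.day_of_year, "value": np.nan,
                         "flag": 1})
        else:
            rows.append({"day_of_year": e.day_of_year,
                         "value": float(fn(e.model)), "flag": 0})
    return pd.DataFrame(rows)


def evaluation_report(table: pd.DataFrame, formulas=("bglm1", "bglm2", "bglm3"),
                      k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Per-model goodness-of-fit and CV metrics (one row per formula)."""
    rows = []
    for f in formulas:
        model = fit_bglm(table, f)
        cv = cross_validate(table, f, k=k, seed=seed)
        rows.append({
            "model": f, "formula": resolve_formula(f),
            "mcfadden_r2": mcfadden_r2(model),
            "auc": cv.metric("auc"), "accuracy": cv.metric("accuracy"),
            "precision": cv.metric("precision"), "recall": cv.metric("recall"),
            "f1": cv.metric("f1"),
            "residual_deviance": model.deviance, "df_resid": model.df_resid,
        })
    return pd.DataFrame(rows)
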