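"""Binomial GLMs of establishment: static fits and the running-window series.

Establishment probability (EP) is modelled on the logit scale as a function
of propagule size (PS, integer covariate), propagule number (PN, categorical
1–3) and spatial environment (SE, categorical site1/site2), with treatment
contrasts (reference PN=1, SE=site1):

* bGLM-1  EP ~ PS
* bGLM-2  EP ~ PS * PN
* bGLM-3  EP ~ PS * PN * SE

The dynamic (running-window) series fits the chosen formula on 90-day
windows of first-introduction day over the two-year design span, advancing
one day per fit: window k covers days [k, k+89] and is indexed to day of
year (k+44) mod 365, yielding exactly 365 models.  Windows with too few
rows or a single outcome class are carried with a degenerate flag instead
of coefficients.  Fitting is maximum likelihood via iteratively reweighted
least squares (statsmodels); intervals are Wald on the link scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

MODEL_FORMULAS = {
    "bglm1": "established ~ PS",
    "bglm2": "established ~ PS * C(PN)",
    "bglm3": "established ~ PS * C(PN) * C(SE)",
}

REQUIRED_COLUMNS = ("PS", "PN", "SE", "intro_day", "established")

#: a coefficient standard error beyond this marks a (quasi-)separated or
#: otherwise unusable logit fit — under separation the MLE diverges and the
#: observed information collapses, inflating Wald SEs by orders of magnitude
_SEPARATION_SE = 50.0


def validate_outcome_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the OutcomeTable contract: required columns, no NA, binary EP."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"outcome table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("outcome table is empty")
    sub = table.loc[:, list(REQUIRED_COLUMNS)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"outcome table has missing values in {bad}")
    if not set(np.unique(table["established"])) <= {0, 1}:
        raise ValueError("established must be binary 0/1")
    return table


def resolve_formula(formula: str) -> str:
    return MODEL_FORMULAS.get(formula, formula)


@dataclass
class FittedModel:
    """A maximum-likelihood binomial GLM and its bookkeeping."""

    formula: str
    params: pd.Series | None
    cov: pd.DataFrame | None
    llf: float
    llnull: float
    deviance: float
    null_deviance: float
    df_resid: float
    nobs: int
    degenerate: bool = False
    reason: str = ""
    fitted: np.ndarray | None = field(default=None, repr=False)
    observed: np.ndarray | None = field(default=None, repr=False)
    design_info: object | None = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [] if self.params is None else list(self.params.index)


def _degenerate(formula: str, nobs: int, reason: str) -> FittedModel:
    return FittedModel(formula=formula, params=None, cov=None, llf=np.nan,
                       llnull=np.nan, deviance=np.nan, null_deviance=np.nan,
                       df_resid=np.nan, nobs=nobs, degenerate=True,
                       reason=reason)


def fit_bglm(table: pd.DataFrame, formula: str = "bglm3") -> FittedModel:
    """Fit a binomial GLM (logit link) of establishment on the table.

    A single-class outcome, non-convergence or complete separation yields a
    flagged degenerate model (coefficients withheld) rather than a crash.
    """
    formula = resolve_formula(formula)
    validate_outcome_table(table) if set(REQUIRED_COLUMNS) <= set(table.columns) \
        else None
    y = table["established"].to_numpy()
    if len(np.unique(y)) < 2:
        return _degenerate(formula, len(table), "single-class outcome")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.formula.glm(formula, data=table,
                                 family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # e.g. perfect separation raised as error
        return _degenerate(formula, len(table), f"fit failed: {exc}")
    params = res.params
    bse = res.bse
    if (not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse))
            or np.max(bse) > _SEPARATION_SE):
        return _degenerate(formula, len(table), "separation detected")
    if not res.converged:
        return _degenerate(formula, len(table), "IRLS did not converge")
    return FittedModel(
        formula=formula,
        params=params,
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=params.index,
                         columns=params.index),
        llf=float(res.llf), llnull=float(res.llnull),
        deviance=float(res.deviance), null_deviance=float(res.null_deviance),
        df_resid=float(res.df_resid), nobs=int(res.nobs),
        fitted=np.asarray(res.fittedvalues), observed=y.astype(float),
        design_info=res.model.data.design_info)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def predict_ep(model: FittedModel, newdata: pd.DataFrame,
               z: float = 1.96) -> pd.DataFrame:
    """Point predictions with 95% Wald intervals mapped through the inverse
    logit, so all outputs lie in [0, 1].  Unseen factor levels are rejected
    with the offending level named.
    """
    if model.degenerate or model.params is None:
        raise ValueError(f"cannot predict from a degenerate model ({model.reason})")
    try:
        (X,) = patsy.build_design_matrices([model.design_info], newdata)
    except patsy.PatsyError as exc:
        raise ValueError(f"prediction data incompatible with training levels: "
                         f"{exc}") from exc
    X = np.asarray(X)
    beta = model.params.to_numpy()
    eta = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, model.cov.to_numpy(), X))
    out = newdata.copy().reset_index(drop=True)
    out["ep"] = _inv_logit(eta)
    out["lo95"] = _inv_logit(eta - z * se)
    out["hi95"] = _inv_logit(eta + z * se)
    return out


def ci_overlap_significance(est1: float, lo1: float, hi1: float,
                            est2: float, lo2: float, hi2: float,
                            tol: float = 1e-9) -> str:
    """Approximate significance from 95% CI overlap.

    Two estimates differ at roughly p = 0.05 when their intervals overlap by
    less than half the length of the shorter proximal interval arm; exactly
    half an arm is the boundary.  Returns ``significant``, ``borderline`` or
    ``not_significant``.
    """
    if est2 < est1:
        est1, lo1, hi1, est2, lo2, hi2 = est2, lo2, hi2, est1, lo1, hi1
    arm1 = hi1 - est1      # upper arm of the lower estimate
    arm2 = est2 - lo2      # lower arm of the higher estimate
    overlap = hi1 - lo2    # negative when disjoint
    half_arm = 0.5 * min(arm1, arm2)
    if abs(overlap - half_arm) <= tol:
        return "borderline"
    return "significant" if overlap < half_arm else "not_significant"


@dataclass
class WindowEntry:
    start_day: int
    day_of_year: int
    model: FittedModel | None
    n_obs: int
    degenerate: bool
    reason: str = ""


@dataclass
class WindowSeries:
    """A day-of-year-indexed sequence of running-window fits."""

    window: int
    step: int
    formula: str
    entries: list[WindowEntry]

    def __len__(self):
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        """Long export ``day_of_year, term, estimate, se, n_obs, degenerate``."""
        rows = []
        for e in self.entries:
            if e.degenerate or e.model is None or e.model.params is None:
                rows.append({"day_of_year": e.day_of_year, "term": "",
                             "estimate": np.nan, "se": np.nan,
                             "n_obs": e.n_obs, "degenerate": 1})
                continue
            se = np.sqrt(np.diag(e.model.cov.to_numpy()))
            for term, est, s in zip(e.model.params.index,
                                    e.model.params.to_numpy(), se):
                rows.append({"day_of_year": e.day_of_year, "term": term,
                             "estimate": est, "se": s, "n_obs": e.n_obs,
                             "degenerate": 0})
        return pd.DataFrame(rows)

    def coefficient_series(self, term: str = "Intercept") -> pd.DataFrame:
        rows = []
        for e in self.entries:
            val = np.nan
            if not e.degenerate and e.model is not None and \
                    term in e.model.params.index:
                val = float(e.model.params[term])
            rows.append({"day_of_year": e.day_of_year, "estimate": val,
                         "degenerate": int(e.degenerate)})
        return pd.DataFrame(rows)


def running_window_fit(table: pd.DataFrame, formula: str = "bglm3",
                       window: int = 90, step: int = 1, n_floor: int = 30,
                       wrap_days: bool = False) -> WindowSeries:
    """Fit the formula on a running window of first-introduction days.

    With the default 90-day window and 1-day step over the 730-day design
    span this produces exactly 365 fitted-or-flagged entries; window k uses
    rows with ``intro_day`` in [k, k+89] and is centred on day k+44.  Windows
    with fewer than ``n_floor`` rows (or one outcome class) are flagged, not
    fitted.  ``wrap_days`` additionally pools rows whose intro day re-enters
    the window modulo 730.
    """
    formula = resolve_formula(formula)
    validate_outcome_table(table)
    span = int(table["intro_day"].max())
    n_windows = max(1, min(365, max(span, window) - window + 1))
    table = table.sort_values("intro_day", kind="stable")
    intro = table["intro_day"].to_numpy()
    entries = []
    for k in range(1, n_windows + 1, step):
        centre = k + (window - 1) // 2
        doy = (centre - 1) % 365 + 1
        mask = (intro >= k) & (intro <= k + window - 1)
        if wrap_days:
            lo = (k - 1) % 730 + 1
            hi = (k + window - 2) % 730 + 1
            if hi < lo:
                mask = (intro >= lo) | (intro <= hi)
        sub = table.loc[mask]
        n_obs = len(sub)
        if n_obs < n_floor:
            entries.append(WindowEntry(k, doy, None, n_obs, True,
                                       f"n_obs {n_obs} below floor {n_floor}"))
            continue
        model = fit_bglm(sub, formula)
        entries.append(WindowEntry(k, doy, None if model.degenerate else model,
                                   n_obs, model.degenerate, model.reason))
    return WindowSeries(window=window, step=step, formula=formula,
                        entries=entries)


def model_summary(model: FittedModel) -> dict:
    """JSON-ready summary: formula, coefficients, SEs, vcov, deviances, n."""
    if model.degenerate:
        return {"formula": model.formula, "degenerate": True,
                "reason": model.reason, "n": model.nobs}
    return {
        "formula": model.formula,
        "degenerate": False,
        "coefficients": model.params.to_dict(),
        "se": {t: float(s) for t, s in zip(model.params.index,
                                           np.sqrt(np.diag(model.cov.to_numpy())))},
        "vcov": model.cov.to_numpy().tolist(),
        "loglik": model.llf,
        "loglik_null": model.llnull,
        "residual_deviance": model.deviance,
        "null_deviance": model.null_deviance,
        "df_resid": model.df_resid,
        "n": model.nobs,
    }
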