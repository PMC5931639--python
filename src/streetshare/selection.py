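"""LOOCV, PRESS-guided variable selection and the final published models.

Model performance is measured by leave-one-out cross-validation: each
city is predicted from a model fitted to the remaining cities, and the
held-out errors are summarised as PRESS (sum of squared errors), MAE
and MDAE (mean/median absolute error, response scale) and — for the
beta family — mean and median absolute standardised errors on the logit
scale, so prediction quality is comparable across outcomes.

Variable selection starts from a maximal model (all road-user presence
counts not essentially uncorrelated with the outcome, plus the month
variables correlated with the presence counts) and sequentially removes
the least significant predictor whenever doing so also reduces the
LOOCV PRESS, stopping when no such removal exists.

``fit_final_models`` reproduces the ten published model specifications
(four Census mode shares, four APS prevalences, two APS days-per-week
measures).  Proportion outcomes stored as percents are divided by 100
before beta fitting; monthly image proportions enter as percents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .regression import (
    FitResult,
    ModelSpec,
    design_matrix,
    fit_model,
    predict,
)

__all__ = [
    "CvResult",
    "SelectionTrace",
    "loocv",
    "correlation_matrix",
    "build_maximal_spec",
    "sequential_elimination",
    "FINAL_MODEL_SPECS",
    "fit_final_models",
    "reproduce_study",
]


@dataclass
class CvResult:
    spec: ModelSpec
    predictions: pd.Series  # held-out response-scale prediction per city
    observed: pd.Series
    press: float  # sum of squared held-out errors
    mae: float
    mdae: float
    mse_std: float | None = None  # mean |standardised error| (beta only)
    mdse_std: float | None = None
    fold_converged: pd.Series | None = None

    @property
    def errors(self) -> pd.Series:
        return self.observed - self.predictions


def _beta_std_error(fit: FitResult, y0: float, x_row: pd.DataFrame) -> float:
    """Standardised held-out error on the logit scale for a beta fold."""
    X0 = design_matrix(fit.spec, x_row)
    mu = special.expit(float((X0 @ fit.params)[0]))
    a, b = mu * fit.phi, (1.0 - mu) * fit.phi
    mustar = special.digamma(a) - special.digamma(b)
    v = special.polygamma(1, a) + special.polygamma(1, b)
    return float((special.logit(y0) - mustar) / np.sqrt(v))


def loocv(spec: ModelSpec, data: pd.DataFrame) -> CvResult:
    """Leave-one-out cross-validation of a fixed model specification."""
    if len(data) < 3:
        raise ValueError("LOOCV needs at least 3 cities")
    preds, obs, conv, std_err = {}, {}, {}, {}
    for idx in data.index:
        train = data.drop(index=idx)
        test = data.loc[[idx]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_model(spec, train)
        except Exception as exc:  # rank deficiency in a fold, etc.
            warnings.warn(f"fold {idx!r} failed: {exc}")
            conv[idx] = False
            continue
        conv[idx] = fit.converged
        if not fit.converged:
            warnings.warn(f"fold {idx!r} did not converge; prediction flagged")
            continue
        preds[idx] = float(predict(fit, test)[0])
        obs[idx] = float(test[spec.outcome].iloc[0])
        if spec.family == "beta":
            std_err[idx] = _beta_std_error(fit, obs[idx], test)
    predictions = pd.Series(preds, name="predicted")
    observed = pd.Series(obs, name="observed")
    err = observed - predictions
    abs_err = err.abs()
    result = CvResult(
        spec=spec,
        predictions=predictions,
        observed=observed,
        press=float((err**2).sum()),
        mae=float(abs_err.mean()),
        mdae=float(abs_err.median()),
        fold_converged=pd.Series(conv),
    )
    if spec.family == "beta" and std_err:
        se = pd.Series(std_err).abs()
        result.mse_std = float(se.mean())
        result.mdse_std = float(se.median())
    return result


def correlation_matrix(data: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Zero-variance columns get NaN in their row and column (their
    diagonal included); all other diagonal entries are exactly 1.
    """
    cols = list(columns) if columns is not None else list(data.columns)
    frame = data[cols].astype(float)
    corr = frame.corr(method="pearson", min_periods=2)
    degenerate = [c for c in cols if frame[c].dropna().nunique() <= 1]
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    for c in cols:
        if c not in degenerate:
            corr.loc[c, c] = 1.0
    return corr


def build_maximal_spec(
    outcome: str,
    data: pd.DataFrame,
    gsv_columns,
    month_columns=(),
    family: str = "beta",
    r_min: float = 0.1,
    transforms: dict | None = None,
) -> ModelSpec:
    """Maximal model: presence counts with |r(outcome)| >= r_min, plus
    month variables whose max |r| with any presence count is >= r_min."""
    transforms = transforms or {}
    cols = [outcome] + list(gsv_columns) + list(month_columns)
    corr = correlation_matrix(data, cols)
    preds = []
    for g in gsv_columns:
        r = corr.loc[outcome, g]
        if np.isfinite(r) and abs(r) >= r_min:
            preds.append((g, transforms.get(g, "identity")))
    for m in month_columns:
        rs = corr.loc[m, list(gsv_columns)].abs()
        if np.isfinite(rs.max()) and rs.max() >= r_min:
            preds.append((m, transforms.get(m, "identity")))
    if not preds:
        warnings.warn(f"no predictor passed |r| >= {r_min} for {outcome!r}; intercept-only")
    return ModelSpec(outcome, tuple(preds), family)


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)  # dicts per candidate tried
    final: ModelSpec | None = None
    final_press: float = np.nan

    def accepted_steps(self):
        return [s for s in self.steps if s["accepted"]]


def sequential_elimination(
    maximal: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> SelectionTrace:
    """Significance-guided, PRESS-minimising backward elimination.

    Repeatedly: among current predictors with Wald p-value above
    ``alpha`` (least significant first; ties broken by the larger PRESS
    reduction, then column order), remove the first whose removal
    lowers the LOOCV PRESS.  Stops when no candidate removal lowers
    PRESS.  Worst case the maximal model is returned unchanged.
    """
    trace = SelectionTrace()
    current = maximal
    current_press = loocv(current, data).press
    while current.predictors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(current, data)
        pvals = fit.pvalues().iloc[1:]  # skip intercept
        pvals.index = [c for c, _ in current.predictors]
        candidates = pvals[pvals > alpha]
        if candidates.empty:
            break
        # evaluate each candidate's PRESS once; order by p desc, then
        # PRESS reduction desc (tie-break), then column order
        order = []
        for col in candidates.index:
            reduced = current.drop(col)
            press = loocv(reduced, data).press
            order.append((col, float(candidates[col]), press))
        order.sort(key=lambda t: (-round(t[1], 12), t[2]))
        accepted = False
        for col, p, press in order:
            ok = press < current_press
            trace.steps.append(
                {
                    "removed": col,
                    "p_value": p,
                    "press_before": current_press,
                    "press_after": press,
                    "accepted": ok,
                }
            )
            if ok:
                current = current.drop(col)
                current_press = press
                accepted = True
                break
        if not accepted:
            break
    trace.final = current
    trace.final_press = current_press
    return trace


# ---------------------------------------------------------------------------
# The ten published model specifications
# ---------------------------------------------------------------------------

#: outcome, predictors, family — outcomes named by their percent columns;
#: beta outcomes are converted to proportions at fit time.
FINAL_MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec("Census_PTWalk", (("GSV_Cycle", "identity"), ("GSV_Bus", "identity"), ("GSV_Mar", "identity")), "beta"),
    2: ModelSpec("Census_Cycle", (("GSV_Cycle", "sqrt"),), "beta"),
    3: ModelSpec("Census_MC", (("GSV_Cycle", "identity"), ("GSV_MC", "identity"), ("GSV_Bus", "identity")), "beta"),
    4: ModelSpec("Census_Car", (("GSV_Cycle", "identity"), ("GSV_Bus", "identity"), ("GSV_Mar", "identity")), "beta"),
    5: ModelSpec("APS_Prev_All_Cycle", (("GSV_Cycle", "identity"), ("GSV_Bus", "identity")), "beta"),
    6: ModelSpec("APS_Prev_Utly_Cycle", (("GSV_Walk", "identity"), ("GSV_Cycle", "identity")), "beta"),
    7: ModelSpec("APS_Prev_All_Walk", (("GSV_Cycle", "identity"), ("GSV_Feb", "identity"), ("GSV_Mar", "identity")), "beta"),
    8: ModelSpec("APS_Prev_Utly_Walk", (("GSV_Cycle", "identity"),), "beta"),
    9: ModelSpec("APS_Days_Utly_Cycle", (("GSV_Cycle", "identity"),), "robust_linear"),
    10: ModelSpec("APS_Days_Utly_Walk", (("GSV_Walk", "identity"),), "ols"),
}

#: percent-scale outcome columns converted to proportions for beta fits
_PERCENT_OUTCOMES = {
    "Census_PTWalk", "Census_Cycle", "Census_MC", "Census_Car",
    "Census_Walk", "Census_Bus",
    "APS_Prev_All_Cycle", "APS_Prev_Utly_Cycle",
    "APS_Prev_All_Walk", "APS_Prev_Utly_Walk",
}


def prepare_model_frame(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Rows and scaling for one model: drops rows with missing values
    and divides percent-scale beta outcomes by 100."""
    cols = [spec.outcome] + [c for c, _ in spec.predictors]
    frame = data[cols].dropna().astype(float).copy()
    if spec.family == "beta" and spec.outcome in _PERCENT_OUTCOMES:
        frame[spec.outcome] = frame[spec.outcome] / 100.0
    return frame


def fit_final_models(data: pd.DataFrame, models=None) -> pd.DataFrame:
    """Fit the published model set and summarise coefficients + LOOCV errors.

    ``data`` is a city-level table in the deposited-dataset dialect
    (percent outcomes, presence counts, monthly percents).  Cities with
    a missing APS block only contribute to the Census models.  Returns
    one row per model with coefficients, precision, PRESS, MAE, MDAE
    and standardised-error summaries.
    """
    models = models or FINAL_MODEL_SPECS
    rows = []
    for model_id, spec in models.items():
        needed = [spec.outcome] + [c for c, _ in spec.predictors]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            warnings.warn(f"model {model_id}: missing columns {missing}; skipped")
            continue
        frame = prepare_model_frame(spec, data)
        if len(frame) < 3:
            warnings.warn(f"model {model_id}: fewer than 3 complete cities; skipped")
            continue
        # a predictor constant across the available cities carries no
        # information and would make the design singular
        for col, _tr in spec.predictors:
            if frame[col].nunique() <= 1:
                warnings.warn(
                    f"model {model_id}: predictor {col!r} has no variance; dropped"
                )
                spec = spec.drop(col)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(spec, frame)
            cv = loocv(spec, frame)
        row = {
            "model": model_id,
            "outcome": spec.outcome,
            "family": spec.family,
            "n": len(frame),
            "converged": fit.converged,
            "(Intercept)": fit.params[0],
            "phi": fit.phi,
            "PRESS": cv.press,
            "MAE": cv.mae,
            "MDAE": cv.mdae,
            "MSR": cv.mse_std,
            "MDSR": cv.mdse_std,
        }
        for name, value in zip(fit.param_names[1:], fit.params[1:]):
            row[name] = value
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def reproduce_study(data: pd.DataFrame) -> dict:
    """End-to-end reproduction on a city-level table: the correlation
    matrix, the ten final models, and the headline cross-validation
    summaries.  Returns a dict of artefacts."""
    gsv = ["GSV_Walk", "GSV_Cycle", "GSV_PCycle", "GSV_Car", "GSV_Bus", "GSV_MC"]
    census = ["Census_Walk", "Census_Cycle", "Census_MC", "Census_Bus",
              "Census_PTWalk", "Census_Car"]
    aps = [c for c in data.columns if c.startswith("APS_") and not c.endswith("_MF")]
    corr = correlation_matrix(data, gsv + census + aps)
    table2 = fit_final_models(data)
    m2_frame = prepare_model_frame(FINAL_MODEL_SPECS[2], data)
    m2_cv = loocv(FINAL_MODEL_SPECS[2], m2_frame)
    return {"correlations": corr, "table2": table2, "model2_cv": m2_cv}
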