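"""Disease-progression scoring from longitudinal UPDRS-III.

A linear mixed model with a per-subject random intercept and random slope
on visit (unstructured 2x2 covariance, REML) is fitted to repeated
UPDRS-III measures, adjusting for age at diagnosis, race/ethnicity,
gender, PD duration at baseline, PD family history, school years and
study wave as fixed effects.  The empirical-Bayes (BLUP) random slope is
then regressed on the same covariates by OLS, and the residual is the
progression measure; the display scale is 1 + residual / SD(residual),
anchoring the cohort mean at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ConvergenceError",
    "ProgressionFit",
    "fit_mixed_model",
    "residualize_slopes",
    "progression_scores",
    "DEFAULT_COVARIATES",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "age_at_diagnosis",
    "ancestry",
    "sex",
    "pd_duration_baseline",
    "family_history",
    "education_years",
    "study_wave",
]

_CATEGORICAL = {"ancestry", "sex", "study_wave"}


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed to converge or was singular."""


@dataclass
class ProgressionFit:
    """REML mixed-model fit: variance components and EB random slopes."""

    eb_slopes: pd.Series          # per-subject BLUP slope deviation
    eb_intercepts: pd.Series
    fixed_effects: pd.Series
    cov_re: pd.DataFrame          # 2x2 random-effects covariance
    scale: float                  # residual variance
    n_subjects: int
    converged: bool
    result: object = None         # underlying statsmodels results

    @property
    def slope_variance(self) -> float:
        return float(self.cov_re.iloc[1, 1])


def _formula(covariates: list[str]) -> str:
    terms = ["visit"]
    for c in covariates:
        terms.append(f"C({c})" if c in _CATEGORICAL else c)
    return "updrs3 ~ " + " + ".join(terms)


def fit_mixed_model(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: list[str] | None = None,
) -> ProgressionFit:
    """Fit the random-intercept/random-slope UPDRS-III model by REML.

    Requires at least two subjects with two or more visits (the slope
    variance is unidentifiable otherwise).  Raises
    :class:`ConvergenceError` if the optimizer does not converge.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    data = visits.merge(subjects, on="subject_id", how="left")
    n_multi = (visits.groupby("subject_id").size() >= 2).sum()
    if n_multi < 2:
        raise ConvergenceError(
            f"only {n_multi} subjects with >= 2 visits; "
            "variance components unidentifiable"
        )
    # drop covariates with a single level (degenerate designs in small sims)
    usable = [
        c for c in covariates
        if c in data.columns and data[c].nunique() > 1
    ]
    model = smf.mixedlm(
        _formula(usable), data, groups=data["subject_id"], re_formula="~visit"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method=["lbfgs", "powell"])
    if not result.converged:
        raise ConvergenceError(
            "REML fit did not converge; "
            f"params={np.asarray(result.params).round(4)}"
        )
    re = result.random_effects
    eb = pd.Series({g: float(v.iloc[1]) for g, v in re.items()}, name="eb_slope")
    eb0 = pd.Series({g: float(v.iloc[0]) for g, v in re.items()}, name="eb_intercept")
    return ProgressionFit(
        eb_slopes=eb.sort_index(),
        eb_intercepts=eb0.sort_index(),
        fixed_effects=result.fe_params,
        cov_re=result.cov_re,
        scale=float(result.scale),
        n_subjects=len(re),
        converged=bool(result.converged),
        result=result,
    )


def _covariate_design(
    subjects: pd.DataFrame, covariates: list[str]
) -> np.ndarray:
    cols = [np.ones(len(subjects))]
    for c in covariates:
        if c not in subjects.columns or subjects[c].nunique() <= 1:
            continue
        if c in _CATEGORICAL:
            dummies = pd.get_dummies(subjects[c], drop_first=True)
            cols.extend(dummies[col].to_numpy(float) for col in dummies)
        else:
            cols.append(subjects[c].to_numpy(float))
    return np.column_stack(cols)


def residualize_slopes(
    eb_slopes: pd.Series,
    subjects: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """OLS-residualize EB slopes on the fixed covariates.

    Residuals have cohort mean zero by construction (intercept included);
    rank-deficient designs are handled by minimum-norm least squares with
    a warning.  Returns subject_id, eb_slope, residual, display_score
    (= 1 + residual / SD(residual)).
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    sub = subjects.set_index("subject_id").loc[eb_slopes.index].reset_index()
    X = _covariate_design(sub, covariates)
    y = eb_slopes.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "covariate design rank-deficient (%d < %d); using min-norm LS",
            rank, X.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    resid = resid - resid.mean()  # exact zero mean
    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
    # residuals at numerical-noise level mean the covariates explain the
    # slopes exactly; treat as degenerate rather than amplifying noise
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        sd = 0.0
    if sd > 0:
        display = 1.0 + resid / sd
    else:
        display = np.ones_like(resid)
    return pd.DataFrame(
        {
            "subject_id": eb_slopes.index,
            "eb_slope": y,
            "residual": resid,
            "display_score": display,
        }
    ).reset_index(drop=True)


def progression_scores(
    visits: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: list[str] | None = None,
    min_visits: int = 2,
) -> tuple[pd.DataFrame, ProgressionFit]:
    """Fit, residualize, and restrict scores to subjects with enough visits.

    All subjects contribute to the fit; a subject "has a progression
    score" only with >= ``min_visits`` visits (shrinkage leaves single-
    visit subjects essentially at the population slope).
    """
    fit = fit_mixed_model(visits, subjects, covariates)
    counts = visits.groupby("subject_id").size()
    scored = counts.index[counts >= min_visits]
    eb = fit.eb_slopes.loc[fit.eb_slopes.index.intersection(scored)]
    scores = residualize_slopes(eb, subjects, covariates)
    return scores, fit
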