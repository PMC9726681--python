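"""Normative statistics: laterality, growth models and z-scores.

Operates on cohort tables (one row per subject: age, sex, left/right MB
volume in mm^3, optionally gestational age at birth / prematurity and
intracranial volume in cm^3). Four analyses mirror the published
normative models:

* laterality — paired comparison of left vs right MB volume, the linear
  map left = a + b*right, and a check that the left-right difference
  does not depend on age or sex;
* neonatal growth — total MB volume vs postmenstrual age at scan
  (weeks) and sex, optionally adding gestational age at birth and a
  prematurity indicator;
* 6-24-year growth — total volume vs age (years) with a quadratic
  term, raw or divided by ICV ("corrected", mm^3 per cm^3);
* normative z-scores for new observations against a fitted curve.

Sex is coded as an indicator male=1, so a positive sex coefficient
means larger volumes in males. Ages enter the design uncentered, which
keeps fitted coefficients directly comparable with the published
equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .volgrid_io import VolGridError

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthFit",
    "LateralityFit",
    "ModelError",
    "fit_ols",
    "analyze_laterality",
    "fit_neonatal_model",
    "fit_growth_quadratic",
    "peak_age",
    "normative_zscore",
    "total_volume",
]


class ModelError(VolGridError):
    """Raised on invalid cohorts or designs."""


@dataclass(frozen=True)
class GrowthFit:
    """Fitted normative regression.

    ``terms`` maps term name -> coefficient; ``residual_sd`` is the
    root mean squared error sqrt(SSR/(n-p)) used for z-scoring;
    ``age_range`` is the observed age span of the fitted cohort (new
    subjects outside it are flagged as extrapolation).
    """

    terms: dict
    std_errors: dict
    t_stats: dict
    p_values: dict
    residual_sd: float
    r_squared: float
    n: int
    age_range: tuple[float, float] | None = None
    response: str = "total_mb_mm3"

    def __post_init__(self):
        keys = list(self.terms)
        for d in (self.std_errors, self.t_stats, self.p_values):
            if list(d) != keys:
                raise ModelError("coefficient tables disagree on term names")
        if self.residual_sd < 0:
            raise ModelError("residual_sd must be >= 0")
        if self.n <= len(keys):
            raise ModelError("need more observations than terms")

    def predict(self, age, male: bool | None = None) -> float:
        """Mean response at ``age`` (and sex, when the fit has a sex term)."""
        t = self.terms
        y = t.get("intercept", 0.0) + t.get("age", 0.0) * age + t.get("age2", 0.0) * age**2
        if "sex_male" in t:
            if male is None:
                y += t["sex_male"] * 0.5  # sex-averaged curve
            elif male:
                y += t["sex_male"]
        return float(y)


@dataclass(frozen=True)
class LateralityFit:
    """Left-vs-right comparison and the left-on-right linear map."""

    slope: float
    intercept: float
    paired_mean_diff_mm3: float
    paired_test_stat: float
    paired_p: float
    diff_vs_age_coeff: float
    diff_vs_age_p: float
    diff_vs_sex_coeff: float
    diff_vs_sex_p: float
    n: int


def _require_columns(cohort: pd.DataFrame, cols) -> None:
    for c in cols:
        if c not in cohort.columns:
            raise ModelError(f"cohort is missing required column '{c}'")
        if cohort[c].isna().any():
            raise ModelError(f"cohort column '{c}' contains missing values")


def total_volume(cohort: pd.DataFrame) -> np.ndarray:
    """Total MB volume (mm^3): left + right, exactly."""
    _require_columns(cohort, ["left_mb_mm3", "right_mb_mm3"])
    return cohort["left_mb_mm3"].to_numpy() + cohort["right_mb_mm3"].to_numpy()


def _male_indicator(cohort: pd.DataFrame) -> np.ndarray:
    sex = cohort["sex"].astype(str).str.lower()
    bad = ~sex.isin(["male", "female", "m", "f"])
    if bad.any():
        raise ModelError(f"unrecognized sex values: {sorted(sex[bad].unique())}")
    return sex.isin(["male", "m"]).to_numpy(dtype=float)


def fit_ols(
    design: np.ndarray,
    response: np.ndarray,
    names: list[str] | None = None,
    age_range: tuple[float, float] | None = None,
    response_name: str = "total_mb_mm3",
) -> GrowthFit:
    """Ordinary least squares with coefficient t-tests.

    ``design`` is the full n x p predictor matrix (include a constant
    column explicitly). Raises :class:`ModelError` on rank deficiency
    or n <= p. Two-sided p-values use the t distribution with n-p
    degrees of freedom.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ModelError(f"design {X.shape} incompatible with response {y.shape}")
    n, p = X.shape
    if n <= p:
        raise ModelError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("design matrix is rank deficient")
    names = names or [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ModelError("one name per design column required")
    res = sm.OLS(y, X).fit()
    return GrowthFit(
        terms=dict(zip(names, res.params)),
        std_errors=dict(zip(names, res.bse)),
        t_stats=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        residual_sd=float(np.sqrt(res.scale)),
        r_squared=float(res.rsquared),
        n=n,
        age_range=age_range,
        response=response_name,
    )


def analyze_laterality(cohort: pd.DataFrame) -> LateralityFit:
    """Paired left-vs-right comparison plus the left-on-right map.

    Performs a paired t-test on (left - right), fits left = a + b*right
    by OLS, and regresses the difference on age and sex to test whether
    the laterality effect depends on either.
    """
    _require_columns(cohort, ["left_mb_mm3", "right_mb_mm3", "age", "sex"])
    n = len(cohort)
    if n < 3:
        raise ModelError(f"laterality analysis needs n >= 3, got {n}")
    left = cohort["left_mb_mm3"].to_numpy(dtype=float)
    right = cohort["right_mb_mm3"].to_numpy(dtype=float)
    diff = left - right

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_rel(left, right)

    X = np.column_stack([np.ones(n), right])
    map_fit = fit_ols(X, left, names=["intercept", "slope"])

    age = cohort["age"].to_numpy(dtype=float)
    male = _male_indicator(cohort)
    Xd = np.column_stack([np.ones(n), age, male])
    if np.linalg.matrix_rank(Xd) < 3:
        dep = GrowthFit(  # degenerate cohort (e.g. single sex): report NaNs
            terms={"intercept": np.nan, "age": np.nan, "sex_male": np.nan},
            std_errors={"intercept": np.nan, "age": np.nan, "sex_male": np.nan},
            t_stats={"intercept": np.nan, "age": np.nan, "sex_male": np.nan},
            p_values={"intercept": np.nan, "age": np.nan, "sex_male": np.nan},
            residual_sd=0.0,
            r_squared=0.0,
            n=n,
        )
    else:
        dep = fit_ols(Xd, diff, names=["intercept", "age", "sex_male"])
    return LateralityFit(
        slope=map_fit.terms["slope"],
        intercept=map_fit.terms["intercept"],
        paired_mean_diff_mm3=float(np.mean(diff)),
        paired_test_stat=float(tstat),
        paired_p=float(pval),
        diff_vs_age_coeff=dep.terms["age"],
        diff_vs_age_p=dep.p_values["age"],
        diff_vs_sex_coeff=dep.terms["sex_male"],
        diff_vs_sex_p=dep.p_values["sex_male"],
        n=n,
    )


def fit_neonatal_model(
    cohort: pd.DataFrame,
    include_ga_birth: bool = False,
    include_prematurity: bool = False,
) -> GrowthFit:
    """Neonatal growth: total volume vs age at scan (weeks) and sex.

    Optionally adds gestational age at birth and/or a prematurity
    indicator as covariates (the published analysis found neither to
    matter). Raises naming the missing column if a requested covariate
    is absent.
    """
    _require_columns(cohort, ["age", "sex"])
    y = total_volume(cohort)
    n = len(cohort)
    cols = [np.ones(n), cohort["age"].to_numpy(dtype=float), _male_indicator(cohort)]
    names = ["intercept", "age", "sex_male"]
    if include_ga_birth:
        _require_columns(cohort, ["ga_birth"])
        cols.append(cohort["ga_birth"].to_numpy(dtype=float))
        names.append("ga_birth")
    if include_prematurity:
        _require_columns(cohort, ["premature"])
        cols.append(cohort["premature"].to_numpy(dtype=float))
        names.append("premature")
    age = cohort["age"].to_numpy(dtype=float)
    return fit_ols(
        np.column_stack(cols), y, names=names, age_range=(age.min(), age.max())
    )


def fit_growth_quadratic(
    cohort: pd.DataFrame, corrected: bool = False, include_sex: bool = False
) -> GrowthFit:
    """6-24-year growth: quadratic-in-age model of total MB volume.

    With ``corrected=True`` the response is total volume divided by ICV
    (mm^3 per cm^3), which requires the ``icv_cm3`` column.
    """
    _require_columns(cohort, ["age"])
    y = total_volume(cohort)
    resp_name = "total_mb_mm3"
    if corrected:
        _require_columns(cohort, ["icv_cm3"])
        icv = cohort["icv_cm3"].to_numpy(dtype=float)
        if np.any(icv <= 0):
            raise ModelError("icv_cm3 must be positive in corrected mode")
        y = y / icv
        resp_name = "corrected_mb_mm3_per_cm3"
    age = cohort["age"].to_numpy(dtype=float)
    n = len(cohort)
    cols = [np.ones(n), age, age**2]
    names = ["intercept", "age", "age2"]
    if include_sex:
        cols.append(_male_indicator(cohort))
        names.append("sex_male")
    return fit_ols(
        np.column_stack(cols),
        y,
        names=names,
        age_range=(age.min(), age.max()),
        response_name=resp_name,
    )


def peak_age(fit: GrowthFit) -> float:
    """Age at the vertex of a fitted concave quadratic: -b / (2c)."""
    if "age" not in fit.terms or "age2" not in fit.terms:
        raise ModelError("fit has no quadratic age terms")
    b, c = fit.terms["age"], fit.terms["age2"]
    if not c < 0:
        raise ModelError(f"quadratic is not concave (age2 coefficient {c})")
    return float(-b / (2.0 * c))


def normative_zscore(
    fit: GrowthFit, age: float, observed_volume: float, male: bool | None = None
) -> tuple[float, float]:
    """Locate an observation within the normative distribution.

    Returns (z, percentile): z = (observed - predicted(age)) /
    residual_sd and the standard-normal percentile of z. Ages outside
    the fitted range are flagged with a warning, not refused.
    """
    if fit.residual_sd == 0:
        raise ModelError("fit has zero residual SD; z-scores are undefined")
    if fit.age_range is not None and not (fit.age_range[0] <= age <= fit.age_range[1]):
        logger.warning(
            "age %.2f outside fitted range [%.2f, %.2f]: extrapolating",
            age,
            *fit.age_range,
        )
    z = (observed_volume - fit.predict(age, male=male)) / fit.residual_sd
    return float(z), float(100.0 * stats.norm.cdf(z))
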