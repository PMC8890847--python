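"""Three-step (Baron-Kenny) mediation analysis with a synthetic-survey generator.

The scientific question: does health literacy *mediate* the negative effect
of depression on daily activity ability in elderly populations?  The
classical three-step test answers it with three ordinary least-squares
regressions on standardized scores:

1. outcome ~ predictor            -> total effect  c
2. mediator ~ predictor           -> path          a
3. outcome ~ predictor + mediator -> direct effect c' and path b

Mediation is *partial* when all paths are significant and |c'| < |c|, and
*full* when the direct effect c' loses significance once the mediator is
included.  The indirect effect is reported descriptively as a*b, and for
OLS fits on one sample the decomposition c = c' + a*b holds exactly.

Because per-subject survey data of this kind are rarely shareable, the
module ships a multivariate-normal survey simulator.  Its default
correlation structure and path coefficients (depression -> health literacy
a = -0.446; health literacy -> outcome b = 0.482; direct effect
c' = -0.388; depression/health-literacy correlation -0.374) emulate a
chronic-disease elderly cohort of n = 382, so estimator behaviour can be
studied by parameter recovery at realistic effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Column order of the three-variable mediation table.
MEDIATION_COLUMNS = ("depression", "health_literacy", "daily_activity")

#: Column order of the four-variable survey table (outcome split into its
#: basic and functional daily-living subscales).
SURVEY_COLUMNS = (
    "basic_daily",
    "functional_daily",
    "health_literacy",
    "depression",
)

#: Default generating correlations among the four survey variables, typical
#: of chronic-disease elderly cohorts: the two daily-living subscales
#: correlate positively with each other and with health literacy, and all
#: three correlate negatively with depression.
DEFAULT_SURVEY_CORR = pd.DataFrame(
    [
        [1.000, 0.610, 0.398, -0.200],
        [0.610, 1.000, 0.563, -0.298],
        [0.398, 0.563, 1.000, -0.374],
        [-0.200, -0.298, -0.374, 1.000],
    ],
    index=list(SURVEY_COLUMNS),
    columns=list(SURVEY_COLUMNS),
)

#: Default survey scale: (mean, sd) per variable for de-standardized output.
#: Health literacy uses the 0-96 composite score scale (57.60 +/- 21.96).
DEFAULT_SURVEY_SCALE = {
    "basic_daily": (80.0, 15.0),
    "functional_daily": (60.0, 18.0),
    "health_literacy": (57.60, 21.96),
    "depression": (40.0, 10.0),
}

_COND_LIMIT = 1e8


@dataclass(frozen=True)
class PathModel:
    """Generating path coefficients of a standardized mediation model.

    All variables have unit population variance: the mediator is
    ``a * X + e_m`` and the outcome ``c' * X + b * M + e_y`` with
    independent normal noise scaled so the variances stay at 1.  The
    implied total effect is ``c = c' + a * b``.
    """

    a: float = -0.446
    b: float = 0.482
    c_prime: float = -0.388

    @property
    def c_total(self) -> float:
        return self.c_prime + self.a * self.b

    @property
    def mediator_noise_sd(self) -> float:
        var = 1.0 - self.a**2
        if var <= 0:
            raise ValueError(f"|a| must be < 1 for a unit-variance mediator, got a={self.a}")
        return float(np.sqrt(var))

    @property
    def outcome_noise_sd(self) -> float:
        var = 1.0 - (self.c_prime**2 + self.b**2 + 2.0 * self.a * self.b * self.c_prime)
        if var <= 0:
            raise ValueError(
                "path coefficients imply outcome variance above 1; no valid noise scale"
            )
        return float(np.sqrt(var))


@dataclass
class SurveyTable:
    """Rectangular table of per-subject scores, one row per subject."""

    data: pd.DataFrame
    standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.data)

    def standardize(self) -> "SurveyTable":
        """Return a copy with each column scaled to mean 0, sd 1 (ddof=1)."""
        z = (self.data - self.data.mean()) / self.data.std(ddof=1)
        return SurveyTable(data=z, standardized=True)


@dataclass(frozen=True)
class RegressionStep:
    """One OLS step: per-coefficient estimates plus fit statistics.

    ``b`` holds raw (unstandardized) slopes, ``beta`` the standardized
    coefficients; ``se`` and ``t`` are identical for both scalings.
    """

    predictors: tuple[str, ...]
    b: np.ndarray
    se: np.ndarray
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    f_value: float


@dataclass(frozen=True)
class MediationFit:
    """Result of the three-step mediation test."""

    step1: RegressionStep
    step2: RegressionStep
    step3: RegressionStep
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    r2_change: float
    verdict: str


def simulate_survey(
    corr: np.ndarray | pd.DataFrame,
    n: int,
    seed: int = 0,
    columns: tuple[str, ...] | None = None,
    rescale: dict[str, tuple[float, float]] | None = None,
) -> SurveyTable:
    """Draw ``n`` subjects from a multivariate normal with correlation ``corr``.

    Draws are standardized (zero mean, unit variance in population) unless
    ``rescale`` maps column names to (mean, sd) pairs.  The matrix must be
    symmetric with unit diagonal and positive semi-definite.
    """
    if isinstance(corr, pd.DataFrame):
        if columns is None:
            columns = tuple(corr.columns)
        corr = corr.to_numpy()
    corr = np.asarray(corr, dtype=np.float64)
    k = corr.shape[0]
    if corr.shape != (k, k) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigmin:.6g})"
        )
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    if columns is None:
        columns = tuple(f"v{i}" for i in range(k))
    if len(columns) != k:
        raise ValueError("number of column names must match the matrix dimension")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(k), corr, size=n, method="eigh")
    df = pd.DataFrame(draws, columns=list(columns))
    standardized = rescale is None
    if rescale is not None:
        for name, (mean, sd) in rescale.items():
            df[name] = df[name] * sd + mean
    return SurveyTable(data=df, standardized=standardized)


def composite_mediation_corr(
    corr: pd.DataFrame = DEFAULT_SURVEY_CORR,
) -> pd.DataFrame:
    """Collapse the two daily-living subscales into one composite outcome.

    The composite is the equally weighted sum of the standardized basic and
    functional subscales, rescaled to unit variance; its correlations with
    the remaining variables follow from the four-variable matrix.  Returns
    the implied 3x3 matrix over (depression, health_literacy,
    daily_activity).
    """
    c = corr.to_numpy()
    b, f, hl, dep = range(4)
    comp_sd = np.sqrt(2.0 + 2.0 * c[b, f])
    r_hl = (c[b, hl] + c[f, hl]) / comp_sd
    r_dep = (c[b, dep] + c[f, dep]) / comp_sd
    out = pd.DataFrame(
        [
            [1.0, c[hl, dep], r_dep],
            [c[hl, dep], 1.0, r_hl],
            [r_dep, r_hl, 1.0],
        ],
        index=list(MEDIATION_COLUMNS),
        columns=list(MEDIATION_COLUMNS),
    )
    return out


def simulate_path_model(model: PathModel, n: int, seed: int = 0) -> SurveyTable:
    """Simulate a standardized mediation data set under ``model``.

    Columns follow :data:`MEDIATION_COLUMNS`; all three variables have unit
    population variance by construction.
    """
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = model.a * x + model.mediator_noise_sd * rng.standard_normal(n)
    y = model.c_prime * x + model.b * m + model.outcome_noise_sd * rng.standard_normal(n)
    df = pd.DataFrame(
        {"depression": x, "health_literacy": m, "daily_activity": y}
    )
    return SurveyTable(data=df, standardized=False)


def pearson_matrix(table: SurveyTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values (t transform, n-2 df)."""
    df = table.data
    n = len(df)
    if n < 4:
        raise ValueError(f"need at least 4 subjects for correlations, got {n}")
    sds = df.std(ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance column(s): {zero_var}")
    r = df.corr(method="pearson")
    rv = r.to_numpy().copy()
    np.clip(rv, -0.9999999999999999, 0.9999999999999999, out=rv)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return r, pd.DataFrame(p, index=r.index, columns=r.columns)


def ols_standardized(y: pd.Series, X: pd.DataFrame) -> RegressionStep:
    """OLS of ``y`` on one or two predictor columns with an intercept.

    Raw slopes are estimated on the data as given; standardized
    coefficients (beta) rescale each slope by sd(x)/sd(y).  The adjusted
    R^2 uses ``1 - (1 - R^2)(n - 1)/(n - p - 1)``.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations for {p} predictors, got {n}")
    design = X.to_numpy()
    if np.linalg.cond(design - design.mean(axis=0)) > _COND_LIMIT:
        raise ValueError("predictors are (nearly) collinear; the fit is not identifiable")
    fit = sm.OLS(np.asarray(y, dtype=np.float64), sm.add_constant(design)).fit()
    b = fit.params[1:]
    sd_y = float(np.std(np.asarray(y, dtype=np.float64), ddof=1))
    sd_x = np.std(design, axis=0, ddof=1)
    beta = b * sd_x / sd_y
    return RegressionStep(
        predictors=tuple(X.columns),
        b=np.asarray(b),
        se=np.asarray(fit.bse[1:]),
        beta=np.asarray(beta),
        t=np.asarray(fit.tvalues[1:]),
        p=np.asarray(fit.pvalues[1:]),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_value=float(fit.fvalue),
    )


def baron_kenny(
    table: SurveyTable,
    alpha_level: float = 0.05,
    predictor: str = "depression",
    mediator: str = "health_literacy",
    outcome: str = "daily_activity",
) -> MediationFit:
    """Run the three-step mediation test on a survey table.

    The table is standardized once (mean 0, sd 1 per column) before the
    three regressions, so the reported path coefficients a, b, c, c' are
    standardized; raw slopes on the standardized data coincide with them.
    The verdict follows the classical logic at the given two-sided
    significance level: ``none`` if any of c, a, b is nonsignificant;
    ``full`` if c' loses significance in step 3; ``partial`` if all paths
    stay significant and |c'| < |c|.
    """
    for name in (predictor, mediator, outcome):
        if name not in table.data.columns:
            raise ValueError(f"table is missing required column {name!r}")
    z = table.data if table.standardized else table.standardize().data

    step1 = ols_standardized(z[outcome], z[[predictor]])
    step2 = ols_standardized(z[mediator], z[[predictor]])
    step3 = ols_standardized(z[outcome], z[[predictor, mediator]])

    c = float(step1.beta[0])
    a = float(step2.beta[0])
    c_prime = float(step3.beta[0])
    b = float(step3.beta[1])

    sig_c = step1.p[0] < alpha_level
    sig_a = step2.p[0] < alpha_level
    sig_b = step3.p[1] < alpha_level
    sig_c_prime = step3.p[0] < alpha_level
    if not (sig_c and sig_a and sig_b):
        verdict = "none"
    elif not sig_c_prime:
        verdict = "full"
    elif abs(c_prime) < abs(c):
        verdict = "partial"
    else:
        verdict = "none"

    return MediationFit(
        step1=step1,
        step2=step2,
        step3=step3,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=a * b,
        r2_change=step3.r2 - step1.r2,
        verdict=verdict,
    )


__all__ = [
    "MEDIATION_COLUMNS",
    "SURVEY_COLUMNS",
    "DEFAULT_SURVEY_CORR",
    "DEFAULT_SURVEY_SCALE",
    "PathModel",
    "SurveyTable",
    "RegressionStep",
    "MediationFit",
    "simulate_survey",
    "composite_mediation_corr",
    "simulate_path_model",
    "pearson_matrix",
    "ols_standardized",
    "baron_kenny",
]
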