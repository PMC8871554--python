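"""Variable-dispersion beta regression of adherence scores on covariates.

The response is a proportion in (0, 1), modelled as Beta(mu*phi, (1-mu)*phi)
with a logit link for the mean mu and a log link for the precision phi, each
with its own linear predictor.  Publication year enters both submodels (the
precision submodel captures changes in score *variability* over time);
journal subject category enters the mean submodel as dummies against a
reference level, and journal impact factor as a continuous covariate.
Model-adjusted category means evaluate the fitted mean at each category's
dummy pattern with every other covariate held at its sample mean.

Maximum-likelihood fitting is delegated to ``statsmodels``' beta-regression
model; this module owns the design construction, Wald and likelihood-ratio
tests, and adjusted means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "ModelSpec",
    "Design",
    "BetaRegressionFit",
    "CoefficientTest",
    "JointTestResult",
    "build_design",
    "fit_beta_regression",
    "fit_trend",
    "coefficient_tests",
    "joint_test",
    "adjusted_means",
    "predicted_mean_curve",
    "compress_boundaries",
]

#: Covariate-name -> data-frame-column translation; "year" is centered.
_COLUMN_FOR = {
    "year": "publication_year",
    "impact_factor": "impact_factor",
    "journal_category": "journal_category",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the mean and precision linear predictors.

    ``year_centering`` is the constant subtracted from publication year
    before it enters either submodel (None: use the sample mean year);
    centering changes only the intercept, not fitted values.
    """

    mean_covariates: tuple[str, ...] = ("year",)
    precision_covariates: tuple[str, ...] = ("year",)
    reference_category: str = "Dermatology"
    year_centering: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_covariates", tuple(self.mean_covariates))
        object.__setattr__(
            self, "precision_covariates", tuple(self.precision_covariates)
        )


@dataclass(frozen=True)
class Design:
    """Response vector and the two design matrices, with column metadata."""

    y: np.ndarray
    X_mean: pd.DataFrame
    Z_precision: pd.DataFrame
    category_levels: tuple[str, ...]  # all levels incl. reference, data order
    reference_category: str | None
    year_centering: float
    compressed: bool


@dataclass(frozen=True)
class CoefficientTest:
    name: str
    estimate: float
    std_error: float
    z: float
    p_two_sided: float


@dataclass(frozen=True)
class JointTestResult:
    name: str
    statistic: float
    df: int
    p_two_sided: float
    method: str = "likelihood_ratio"


@dataclass(frozen=True)
class BetaRegressionFit:
    """ML estimates for both submodels plus everything needed for inference."""

    beta: pd.Series  # mean submodel, logit link
    gamma: pd.Series  # precision submodel, log link
    loglik: float
    covariance: pd.DataFrame  # over (beta, gamma), inverse observed information
    converged: bool
    n: int
    design: Design | None = None
    _y: np.ndarray = field(default=None, repr=False, compare=False)
    _X: pd.DataFrame = field(default=None, repr=False, compare=False)
    _Z: pd.DataFrame = field(default=None, repr=False, compare=False)

    @property
    def params(self) -> pd.Series:
        g = self.gamma.copy()
        g.index = ["precision:" + c for c in g.index]
        b = self.beta.copy()
        b.index = ["mean:" + c for c in b.index]
        return pd.concat([b, g])

    def fitted_mean(self, X: pd.DataFrame | np.ndarray | None = None) -> np.ndarray:
        X = self._X if X is None else X
        eta = np.asarray(X, dtype=float) @ self.beta.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def fitted_precision(self, Z=None) -> np.ndarray:
        Z = self._Z if Z is None else Z
        return np.exp(np.asarray(Z, dtype=float) @ self.gamma.to_numpy())


def compress_boundaries(y: np.ndarray) -> np.ndarray:
    """Shrink a [0, 1] sample strictly inside the open interval.

    Applies the standard compression (y*(n-1) + 0.5) / n to the whole
    sample, preserving order; used only when 0 or 1 actually occur.
    """
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    *,
    boundary_compression: bool = False,
) -> Design:
    """Assemble response and design matrices from a study-level score table.

    ``df`` needs a ``score`` column plus the columns behind the requested
    covariates (``publication_year``, ``journal_category``,
    ``impact_factor``).  Categorical covariates are dummy-coded against
    ``spec.reference_category``; year is centered.  Scores of exactly 0 or
    1 are outside the beta support: they raise an error unless
    ``boundary_compression`` is on, in which case the whole sample is
    compressed and the design flagged accordingly.
    """
    y = df["score"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("scores must lie in [0, 1]")
    compressed = False
    if np.any((y == 0) | (y == 1)):
        if not boundary_compression:
            raise ValueError(
                "scores of exactly 0 or 1 lie outside the open-interval "
                "support of the beta distribution; enable boundary_compression"
            )
        y = compress_boundaries(y)
        compressed = True

    year_centering = spec.year_centering
    if year_centering is None:
        year_centering = float(df["publication_year"].mean())

    category_levels: tuple[str, ...] = ()
    reference = None

    def columns_for(covariates: Sequence[str]) -> pd.DataFrame:
        nonlocal category_levels, reference
        out = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
        for name in covariates:
            if name == "year":
                out["year"] = (
                    df["publication_year"].to_numpy(dtype=float) - year_centering
                )
            elif name == "journal_category":
                levels = tuple(pd.unique(df["journal_category"]))
                if spec.reference_category not in levels:
                    raise ValueError(
                        f"reference category {spec.reference_category!r} "
                        "absent from the data"
                    )
                category_levels = levels
                reference = spec.reference_category
                for lvl in levels:
                    if lvl == reference:
                        continue
                    out[f"journal_category[{lvl}]"] = (
                        df["journal_category"] == lvl
                    ).to_numpy(dtype=float)
            elif name in _COLUMN_FOR:
                out[name] = df[_COLUMN_FOR[name]].to_numpy(dtype=float)
            elif name in df.columns:
                out[name] = df[name].to_numpy(dtype=float)
            else:
                raise ValueError(f"unknown covariate {name!r}")
        return out

    X = columns_for(spec.mean_covariates)
    Z = columns_for(spec.precision_covariates)
    return Design(
        y=y,
        X_mean=X,
        Z_precision=Z,
        category_levels=category_levels,
        reference_category=reference,
        year_centering=year_centering,
        compressed=compressed,
    )


def fit_beta_regression(
    y: np.ndarray,
    X_mean: pd.DataFrame,
    Z_precision: pd.DataFrame,
    design: Design | None = None,
) -> BetaRegressionFit:
    """Maximum-likelihood fit of the two-submodel beta regression.

    The covariance is the inverse observed information at the optimum; the
    ``converged`` flag reflects the optimizer's own status and a
    non-convergent fit is returned flagged rather than raised.
    """
    X_mean = pd.DataFrame(X_mean)
    Z_precision = pd.DataFrame(Z_precision)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k, m = X_mean.shape[1], Z_precision.shape[1]
    if n <= k + m:
        raise ValueError(
            f"n = {n} observations cannot identify {k + m} parameters"
        )
    for label, M in (("mean", X_mean), ("precision", Z_precision)):
        if np.linalg.matrix_rank(M.to_numpy(dtype=float)) < M.shape[1]:
            raise ValueError(f"{label} design matrix is rank deficient")

    model = BetaModel(
        y, X_mean.to_numpy(dtype=float),
        exog_precision=Z_precision.to_numpy(dtype=float),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
        # polish to a tight gradient norm so results are invariant to
        # reparameterisations such as shifting the year centering
        res = model.fit(
            start_params=res.params, method="bfgs", gtol=1e-10,
            maxiter=200, disp=False,
        )
    # honest convergence flag: judge the actual score norm at the optimum
    # rather than the optimizer's own status (tight-gtol BFGS can stop on
    # precision loss with the gradient already numerically zero)
    grad = np.asarray(model.score(res.params))
    converged = bool(np.all(np.isfinite(grad)) and np.max(np.abs(grad)) < 1e-3)

    names = [f"mean:{c}" for c in X_mean.columns] + [
        f"precision:{c}" for c in Z_precision.columns
    ]
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return BetaRegressionFit(
        beta=pd.Series(res.params[:k], index=list(X_mean.columns)),
        gamma=pd.Series(res.params[k:], index=list(Z_precision.columns)),
        loglik=float(res.llf),
        covariance=cov,
        converged=converged,
        n=n,
        design=design,
        _y=y,
        _X=X_mean,
        _Z=Z_precision,
    )


def fit_trend(
    df: pd.DataFrame,
    spec: ModelSpec | None = None,
    *,
    boundary_compression: bool = False,
) -> BetaRegressionFit:
    """Build the design from a score table and fit in one step."""
    spec = spec or ModelSpec()
    design = build_design(df, spec, boundary_compression=boundary_compression)
    return fit_beta_regression(
        design.y, design.X_mean, design.Z_precision, design=design
    )


def coefficient_tests(fit: BetaRegressionFit) -> list[CoefficientTest]:
    """Wald z-test for each coefficient of both submodels."""
    if not fit.converged:
        raise ValueError("coefficient tests require a converged fit")
    se = np.sqrt(np.diag(fit.covariance.to_numpy()))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("singular covariance; standard errors undefined")
    out = []
    params = fit.params
    for name, est, s in zip(params.index, params.to_numpy(), se):
        z = est / s
        out.append(
            CoefficientTest(
                name=name,
                estimate=float(est),
                std_error=float(s),
                z=float(z),
                p_two_sided=float(2 * sps.norm.sf(abs(z))),
            )
        )
    return out


def joint_test(fit: BetaRegressionFit, columns: Sequence[str]) -> JointTestResult:
    """Likelihood-ratio test that a group of mean-submodel columns is zero.

    Refits the model without the named columns (e.g. the dummy block of a
    categorical covariate) and refers 2 * (ll_full - ll_null) to chi-squared
    with one degree of freedom per dropped column.
    """
    if not fit.converged:
        raise ValueError("joint test requires a converged fit")
    columns = list(columns)
    missing = [c for c in columns if c not in fit._X.columns]
    if missing:
        raise ValueError(f"columns not in the mean design: {missing}")
    X_null = fit._X.drop(columns=columns)
    null_fit = fit_beta_regression(fit._y, X_null, fit._Z)
    stat = 2.0 * (fit.loglik - null_fit.loglik)
    df = len(columns)
    return JointTestResult(
        name="+".join(columns),
        statistic=float(max(stat, 0.0)),
        df=df,
        p_two_sided=float(sps.chi2.sf(max(stat, 0.0), df)),
    )


def category_columns(fit: BetaRegressionFit) -> list[str]:
    """Mean-design dummy columns of the categorical covariate."""
    return [c for c in fit._X.columns if c.startswith("journal_category[")]


def adjusted_means(fit: BetaRegressionFit) -> dict[str, float]:
    """Model-adjusted mean score per category at the mean covariate pattern.

    For each category level (including the reference) the mean linear
    predictor uses that level's dummy pattern with every other mean-submodel
    covariate at its sample mean; the adjusted mean is the inverse logit.
    """
    if fit.design is None or not fit.design.category_levels:
        raise ValueError(
            "fit carries no categorical covariate; fit via fit_trend with "
            "'journal_category' among the mean covariates"
        )
    dummies = category_columns(fit)
    base = fit._X.mean(axis=0)
    out: dict[str, float] = {}
    for lvl in fit.design.category_levels:
        row = base.copy()
        for c in dummies:
            row[c] = 0.0
        if lvl != fit.design.reference_category:
            col = f"journal_category[{lvl}]"
            if col not in row.index:
                raise ValueError(f"category level {lvl!r} absent from the fit")
            row[col] = 1.0
        eta = float(row.to_numpy() @ fit.beta.to_numpy())
        out[lvl] = 1.0 / (1.0 + np.exp(-eta))
    return out


def predicted_mean_curve(
    fit: BetaRegressionFit, years: Sequence[float]
) -> pd.DataFrame:
    """Fitted mean score over a year grid at the mean pattern of the other
    covariates — the plot-ready temporal-trend curve."""
    if fit.design is None or "year" not in fit._X.columns:
        raise ValueError("fit has no year covariate in the mean submodel")
    base = fit._X.mean(axis=0)
    rows = []
    for yr in years:
        row = base.copy()
        row["year"] = yr - fit.design.year_centering
        eta = float(row.to_numpy() @ fit.beta.to_numpy())
        rows.append((yr, 1.0 / (1.0 + np.exp(-eta))))
    return pd.DataFrame(rows, columns=["publication_year", "predicted_mean"])
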