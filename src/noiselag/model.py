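"""Binomial logistic model for areal call occurrence.

The response is the dichotomized call indicator of a (unit, date, period)
cell and the linear predictor combines calendar terms (weekday, month,
period), six spatio-temporal lag indicators, a district factor capturing
residual spatial heterogeneity, and unit-level covariates:

    logit P(noisebin = 1) = b0 + b_weekday + b_month + b_period
                            + b1*noisebin1 + ... + b6*noisebin22
                            + b_district + sum_k b_k * x_k

Categorical terms enter through treatment coding (J-1 indicators against a
reference level: Sunday, June, the day period and the first district), the
population size enters as its natural logarithm, and the fit is by maximum
likelihood via iteratively reweighted least squares (Newton-Raphson on the
Bernoulli log-likelihood).  exp(beta) is the multiplicative change in the
odds of a call per unit change of the covariate; 95% confidence bounds use
the fixed Wald multiplier 1.96 on the log-odds scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.special import expit

from .lattice import LatticeGraph
from .panel import LAG_COLUMNS

__all__ = [
    "WEEKDAY_LEVELS",
    "MONTH_LEVELS",
    "NUMERIC_TERMS",
    "TERM_ORDER",
    "DesignSpec",
    "Design",
    "LogisticFit",
    "RankDeficiencyError",
    "SeparationError",
    "ConvergenceError",
    "build_design",
    "fit_logistic",
    "fit_design",
    "odds_ratio_table",
    "interpret_numeric_change",
    "sequential_deviance",
    "predict_probability",
    "probability_map",
    "covariate_correlation",
    "CorrelationResult",
    "read_covariates_csv",
    "write_covariates_csv",
]

WEEKDAY_LEVELS = (
    "Monday",
    "Tuesday",
    "Wednesday",
    "Thursday",
    "Friday",
    "Saturday",
    "Sunday",
)
MONTH_LEVELS = (
    "January",
    "February",
    "March",
    "April",
    "May",
    "June",
    "July",
    "August",
    "September",
    "October",
    "November",
    "December",
)
#: numeric covariate terms in model order; log_inhab is ln(inhabitants)
NUMERIC_TERMS = (
    "log_inhab",
    "inhab14",
    "inhab1529",
    "inhab65",
    "mphouse",
    "barrest",
    "svi",
    "mainroad",
    "buildage",
    "educuse",
    "greenuse",
    "botellon",
)
#: model terms in design order
TERM_ORDER = ("weekday", "month", "period") + LAG_COLUMNS + ("district",) + NUMERIC_TERMS

COVARIATE_COLUMNS = (
    "unit_id",
    "year",
    "district",
    "inhab",
    "inhab14",
    "inhab1529",
    "inhab65",
    "mphouse",
    "barrest",
    "svi",
    "mainroad",
    "buildage",
    "educuse",
    "greenuse",
    "botellon",
)


class RankDeficiencyError(ValueError):
    """Design matrix is not of full column rank."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration cap."""


@dataclass(frozen=True)
class DesignSpec:
    """Reference levels and coding conventions of the design matrix.

    ``reference_district=None`` means the first district in sorted order.
    """

    reference_weekday: str = "Sunday"
    reference_month: str = "June"
    reference_period: str = "day"
    reference_district: str | None = None


@dataclass
class Design:
    """Assembled design matrix with named columns and per-term slices."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    term_slices: dict[str, slice]
    spec: DesignSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        """Columns of the intercept plus the given terms, in design order."""
        cols = [0]
        names = ["intercept"]
        for t in terms:
            sl = self.term_slices[t]
            cols.extend(range(sl.start, sl.stop))
            names.extend(self.columns[sl])
        return self.X[:, cols], names


def build_design(
    panel_df: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: DesignSpec = DesignSpec(),
) -> Design:
    """Assemble the design matrix and response from a trimmed panel.

    Weekday and month derive from each record's calendar date; covariates
    join on (unit, calendar year).  Categorical terms are treatment-coded
    with the spec's reference levels; the full weekday/month/period level
    sets are always emitted so two panels over the same units yield
    column-compatible designs regardless of which dates they cover.
    """
    df = panel_df
    lag_vals = df[list(LAG_COLUMNS)]
    if lag_vals.isna().any().any():
        raise ValueError("panel contains undefined lags; apply trim_for_lags first")

    dates = pd.to_datetime(df["date"])
    weekday = dates.dt.weekday.to_numpy()  # 0 = Monday
    month = (dates.dt.month - 1).to_numpy()  # 0 = January
    year = dates.dt.year

    cov = covariates.set_index(["unit_id", "year"])
    if cov.index.has_duplicates:
        raise ValueError("duplicate (unit_id, year) rows in covariate table")
    keys = pd.MultiIndex.from_arrays([df["unit_id"], year])
    try:
        joined = cov.reindex(keys)
    except Exception as exc:  # pragma: no cover - reindex rarely raises
        raise ValueError(f"covariate join failed: {exc}") from exc
    missing = joined["inhab"].isna()
    if missing.any():
        bad = sorted(set(keys[missing.to_numpy()]))[:10]
        raise ValueError(f"missing covariate records for (unit, year): {bad}")
    inhab = joined["inhab"].to_numpy(dtype=float)
    if (inhab <= 0).any():
        bad = sorted(set(df["unit_id"].to_numpy()[inhab <= 0]))
        raise ValueError(f"non-positive inhab for units {bad}; log is undefined")

    districts = sorted(covariates["district"].astype(str).unique())
    ref_district = spec.reference_district or districts[0]
    if ref_district not in districts:
        raise ValueError(f"reference district {ref_district!r} not present")
    unit_district = joined["district"].astype(str).to_numpy()

    n = len(df)
    columns: list[str] = ["intercept"]
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    term_slices: dict[str, slice] = {"intercept": slice(0, 1)}
    pos = 1

    def add_block(term: str, block: np.ndarray, names: list[str]) -> None:
        nonlocal pos
        blocks.append(block)
        columns.extend(names)
        term_slices[term] = slice(pos, pos + block.shape[1])
        pos += block.shape[1]

    def dummies(codes: np.ndarray, levels: Sequence[str], ref: str, term: str) -> None:
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} unknown for term {term!r}")
        keep = [lv for lv in levels if lv != ref]
        block = np.zeros((n, len(keep)))
        lvl_index = {lv: k for k, lv in enumerate(levels)}
        for k, lv in enumerate(keep):
            block[:, k] = codes == lvl_index[lv]
        add_block(term, block, [f"{term}[{lv}]" for lv in keep])

    dummies(weekday, list(WEEKDAY_LEVELS), spec.reference_weekday, "weekday")
    dummies(month, list(MONTH_LEVELS), spec.reference_month, "month")
    period_codes = (df["period"].to_numpy() == "night").astype(int)
    dummies(period_codes, ["day", "night"], spec.reference_period, "period")

    for lagcol in LAG_COLUMNS:
        add_block(lagcol, df[lagcol].to_numpy(dtype=float)[:, None], [lagcol])

    district_codes = np.searchsorted(districts, unit_district)
    dummies(district_codes, districts, ref_district, "district")

    add_block("log_inhab", np.log(inhab)[:, None], ["log_inhab"])
    for term in NUMERIC_TERMS[1:]:
        add_block(term, joined[term].to_numpy(dtype=float)[:, None], [term])

    X = np.hstack(blocks)
    y = df["noisebin"].to_numpy(dtype=float)
    return Design(X=X, y=y, columns=columns, term_slices=term_slices, spec=spec)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``params`` is on the log-odds scale; standard errors come from the
    inverse observed information at the optimum.
    """

    columns: list[str]
    params: np.ndarray
    se: np.ndarray
    loglik: float
    deviance: float
    null_deviance: float
    df_resid: int
    n_obs: int
    n_iter: int
    converged: bool
    term_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def pvalues(self) -> np.ndarray:
        z = np.divide(self.params, self.se, out=np.zeros_like(self.params), where=self.se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef(self, name: str) -> float:
        return float(self.params[self.columns.index(name)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.params)


def _bernoulli_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    # -2 loglik; the saturated log-likelihood of a Bernoulli response is 0
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _null_deviance(y: np.ndarray) -> float:
    n = y.size
    k = float(y.sum())
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return -2.0 * (k * math.log(p) + (n - k) * math.log(1.0 - p))


def _diagnose_rank(X: np.ndarray, columns: Sequence[str] | None) -> list[str]:
    # name every column with weight in the null space, so all members of a
    # collinear group appear in the message, not just the last-pivoted one
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = (s.max() if s.size else 0.0) * max(X.shape) * np.finfo(float).eps
    null_vecs = vt[s <= tol]
    if null_vecs.size == 0:
        null_vecs = vt[-1:]
    involved = np.flatnonzero(np.abs(null_vecs).max(axis=0) > 1e-8)
    if columns is None:
        return [f"column {k}" for k in involved]
    return [columns[k] for k in involved]


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str] | None = None,
    *,
    tol_score: float = 1e-8,
    tol_dev: float = 1e-12,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
    term_slices: Mapping[str, slice] | None = None,
) -> LogisticFit:
    """Fit a logistic regression by Newton-Raphson IRLS.

    Stops when the largest score component falls below ``tol_score`` or the
    relative deviance change falls below ``tol_dev``.  A rank-deficient
    design raises :class:`RankDeficiencyError` naming the collinear columns;
    (quasi-)complete separation — detected as a diverging coefficient norm
    while the gradient refuses to vanish — raises :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-d with one row per response element")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    n, p = X.shape
    cols = list(columns) if columns is not None else [f"x{k}" for k in range(p)]

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = X @ beta
    dev = _bernoulli_deviance(eta, y)
    converged = False
    it = 0
    chol = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        max_score = float(np.abs(score).max())
        if max_score < tol_score:
            converged = True
            break
        xtwx = (X * w[:, None]).T @ X
        try:
            chol = sla.cho_factor(xtwx)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            raise RankDeficiencyError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_diagnose_rank(X, cols))
            ) from None
        step = sla.cho_solve(chol, score)
        # step-halving keeps Newton monotone on ill-scaled problems
        new_beta = beta + step
        new_eta = X @ new_beta
        new_dev = _bernoulli_deviance(new_eta, y)
        halvings = 0
        while new_dev > dev + 1e-10 and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_eta = X @ new_beta
            new_dev = _bernoulli_deviance(new_eta, y)
            halvings += 1
        beta, eta = new_beta, new_eta
        rel_change = abs(dev - new_dev) / (abs(dev) + 1.0)
        dev = new_dev
        if rel_change < tol_dev:
            # likelihood is flat; either converged or the MLE is at infinity
            if max_score < 1e-4 * (1.0 + abs(dev)):
                converged = True
            break
    max_beta = float(np.abs(beta).max())
    saturated = np.abs(eta) > 20.0
    if max_beta > 30.0 or (
        max_beta > 10.0
        and saturated.any()
        and bool(np.all((2.0 * y[saturated] - 1.0) * eta[saturated] > 0))
    ):
        raise SeparationError(
            "coefficients diverging with saturated fitted probabilities: "
            "complete or quasi-complete separation; the maximum-likelihood "
            "estimate does not exist"
        )
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {it} iterations")

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    xtwx = (X * w[:, None]).T @ X
    try:
        chol = sla.cho_factor(xtwx)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(_diagnose_rank(X, cols))
        ) from None
    cov = sla.cho_solve(chol, np.eye(p))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    dev = _bernoulli_deviance(eta, y)
    return LogisticFit(
        columns=cols,
        params=beta,
        se=se,
        loglik=-0.5 * dev,
        deviance=dev,
        null_deviance=_null_deviance(y),
        df_resid=n - p,
        n_obs=n,
        n_iter=it,
        converged=converged,
        term_slices=dict(term_slices) if term_slices is not None else {},
    )


def fit_design(design: Design, **kwargs) -> LogisticFit:
    """Convenience wrapper: fit the full model of an assembled design."""
    return fit_logistic(
        design.X, design.y, design.columns, term_slices=design.term_slices, **kwargs
    )


# ---------------------------------------------------------------------------
# reporting


def odds_ratio_table(fit: LogisticFit, z: float = 1.96) -> pd.DataFrame:
    """Coefficients with odds ratios and Wald 95% confidence bounds.

    Columns mirror the conventional logistic-regression report: beta, SE,
    p-value, exp(beta) and the CI ``exp(beta -/+ 1.96*SE)``.
    """
    if not fit.converged:
        raise ValueError("odds ratios require a converged fit")
    beta = fit.params
    se = fit.se
    return pd.DataFrame(
        {
            "term": fit.columns,
            "beta": beta,
            "se": se,
            "p_value": fit.pvalues,
            "odds_ratio": np.exp(beta),
            "ci_lower": np.exp(beta - z * se),
            "ci_upper": np.exp(beta + z * se),
        }
    )


def interpret_numeric_change(
    beta: float, change: float, *, variable_on_log_scale: bool = False
) -> float:
    """Odds-ratio change for a covariate movement.

    For a log-transformed covariate, ``change`` is the multiplicative factor
    applied to the raw variable (e.g. 1.10 for a 10% increase) and the
    result is ``exp(beta * ln(change))``.  For an untransformed covariate,
    ``change`` is the additive shift ``delta`` and the result is
    ``exp(beta * delta)``.
    """
    if variable_on_log_scale:
        if change <= 0:
            raise ValueError("multiplicative change must be > 0")
        return float(math.exp(beta * math.log(change)))
    return float(math.exp(beta * change))


def sequential_deviance(
    design: Design,
    order: Sequence[str] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Analysis of deviance for the nested sequence of models.

    Starting from the intercept-only (NULL) model, terms are added one at a
    time in ``order`` (default: design order with the district factor last,
    so the sequence of residual degrees of freedom is monotone) and each
    row reports the term's degrees of freedom, the deviance reduction, the
    residual df/deviance of the enlarged model and the chi-square upper-tail
    p-value of the reduction.
    """
    terms = [t for t in design.term_slices if t != "intercept"]
    if order is None:
        order = [t for t in terms if t != "district"] + (
            ["district"] if "district" in terms else []
        )
    else:
        order = list(order)
        unknown = set(order) - set(terms)
        if unknown:
            raise ValueError(f"unknown terms in deviance order: {sorted(unknown)}")

    y = design.y
    rows = []
    null_dev = _null_deviance(y)
    prev_dev = null_dev
    prev_df = design.n - 1
    rows.append(
        {
            "term": "NULL",
            "df": np.nan,
            "deviance": np.nan,
            "resid_df": prev_df,
            "resid_dev": null_dev,
            "p_value": np.nan,
        }
    )
    included: list[str] = []
    beta_prev: np.ndarray | None = None
    for term in order:
        included.append(term)
        Xsub, names = design.subset(included)
        beta0 = None
        if beta_prev is not None:
            beta0 = np.zeros(Xsub.shape[1])
            beta0[: beta_prev.size] = beta_prev
        fit = fit_logistic(Xsub, y, names, beta0=beta0, **fit_kwargs)
        beta_prev = fit.params
        drop = prev_dev - fit.deviance
        df_term = prev_df - fit.df_resid
        rows.append(
            {
                "term": term,
                "df": df_term,
                "deviance": drop,
                "resid_df": fit.df_resid,
                "resid_dev": fit.deviance,
                "p_value": float(stats.chi2.sf(max(drop, 0.0), df_term)),
            }
        )
        prev_dev = fit.deviance
        prev_df = fit.df_resid
    return pd.DataFrame(rows)


def predict_probability(fit: LogisticFit, x: np.ndarray) -> np.ndarray:
    """Inverse-logit probability for design row(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return float(expit(x @ fit.params))
    return fit.predict(x)


def probability_map(
    fit: LogisticFit,
    lattice: LatticeGraph,
    panel_df: pd.DataFrame,
    covariates: pd.DataFrame,
    scenario: Mapping[str, object],
    spec: DesignSpec = DesignSpec(),
    k: int = 5,
) -> pd.DataFrame:
    """Per-unit call probability under a calendar scenario.

    ``scenario`` names a weekday, month, period and year; the lag history
    for every unit is taken from the most recent panel date inside the
    scenario year whose weekday/month match the scenario (so the map uses
    the realized recent history exactly as the model would in operation).
    Returns one row per unit with the probability, its descending rank and a
    flag for the ``k`` highest-probability units.
    """
    weekday = str(scenario["weekday"])
    month = str(scenario["month"])
    period = str(scenario["period"])
    year = int(scenario["year"])
    if weekday not in WEEKDAY_LEVELS:
        raise ValueError(f"unknown weekday {weekday!r}")
    if month not in MONTH_LEVELS:
        raise ValueError(f"unknown month {month!r}")
    if period not in ("day", "night"):
        raise ValueError(f"unknown period {period!r}")

    df = panel_df
    dates = pd.to_datetime(df["date"])
    mask = (
        (dates.dt.year == year)
        & (dates.dt.weekday == WEEKDAY_LEVELS.index(weekday))
        & (dates.dt.month == MONTH_LEVELS.index(month) + 1)
        & (df["period"] == period)
        & (df["date_index"] > 14)
    )
    if not mask.any():
        raise ValueError(
            f"no panel records match scenario {weekday}/{month}/{period}/{year}"
        )
    d_star = int(df.loc[mask, "date_index"].max())
    sub = df[mask & (df["date_index"] == d_star)].copy()
    sub = sub.set_index("unit_id").reindex(list(lattice.unit_ids)).reset_index()
    if sub["date_index"].isna().any():
        missing = sub.loc[sub["date_index"].isna(), "unit_id"].tolist()
        raise ValueError(f"panel incomplete for units {missing} at date {d_star}")

    design = build_design(sub, covariates, spec)
    if design.columns != fit.columns:
        raise ValueError("scenario design columns do not match the fitted model")
    probs = fit.predict(design.X)
    order = np.argsort(-probs, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(probs) + 1)
    return pd.DataFrame(
        {
            "unit_id": list(lattice.unit_ids),
            "probability": probs,
            "rank": rank,
            "top_k": rank <= k,
        }
    )


@dataclass
class CorrelationResult:
    """Pearson correlations among unit covariates with a significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    masked: pd.DataFrame  # r where p < alpha (diagonal kept), NaN elsewhere
    alpha: float


def covariate_correlation(
    covariates: pd.DataFrame, alpha: float = 0.05
) -> CorrelationResult:
    """Significance-masked Pearson correlation matrix of unit covariates.

    Correlations whose two-sided t-test p-value is at least ``alpha`` are
    masked (NaN).  Constant columns cannot be correlated; they are masked
    entirely with a warning.
    """
    numeric = [c for c in COVARIATE_COLUMNS if c not in ("unit_id", "year", "district")]
    cols = [c for c in numeric if c in covariates.columns]
    data = covariates[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to test correlations")
    sd = data.std(axis=0)
    constant = sd == 0
    if constant.any():
        bad = [cols[k] for k in np.flatnonzero(constant)]
        warnings.warn(f"constant covariate columns masked: {bad}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    masked = np.where(p < alpha, r, np.nan)
    np.fill_diagonal(masked, 1.0)
    masked[constant, :] = np.nan
    masked[:, constant] = np.nan
    idx = pd.Index(cols)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        masked=pd.DataFrame(masked, index=idx, columns=idx),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "district": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    return df


def write_covariates_csv(covariates: pd.DataFrame, path) -> None:
    covariates[list(COVARIATE_COLUMNS)].to_csv(path, index=False)
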