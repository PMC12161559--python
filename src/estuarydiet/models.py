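"""Gamma log-link regression of the per-fish ration scores, with AICc,
estimated marginal means, and pairwise comparisons.

The responses (IR, ER, Jm) are strictly positive, continuous and right
skewed, so they are modeled as gamma with a log link, parameterized by
mean mu and dispersion alpha: shape = 1/alpha, scale = mu * alpha, hence
Var(x) = alpha * mu^2.  Coefficients are maximum likelihood via IRLS;
alpha is profiled out by a one-dimensional ML step given the fitted
means.  Wald covariance of beta is alpha * (X'X)^{-1} (the gamma/log-link
Fisher information has unit working weights).

Year-to-year (and optionally month-within-year) variation enters as
fixed blocking dummies rather than random intercepts; the estimands of
interest -- factor-level marginal means and their contrasts -- are
unchanged by that choice, and competing blocking structures can be ranked
by AICc.

Cohen's d for a contrast is the link-scale difference of marginal means
divided by a population SD.  The default SD is the model's link-scale
residual SD, sqrt(trigamma(1/alpha)) -- the variance of log(x) for a
gamma variate -- and it is a pluggable choice (``sigma_pop``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.special
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EmmResult",
    "fit_gamma_loglink",
    "aicc",
    "estimated_marginal_means",
    "pairwise_comparisons",
]

RESPONSES = ("ir", "er", "jm")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model and with which fixed factors / blocking."""

    response: str
    factors: tuple[str, ...]
    blocking: str = "year"  # none | year | year_month
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if not self.factors:
            raise ValueError("at least one fixed factor is required")
        if self.blocking not in ("none", "year", "year_month"):
            raise ValueError("blocking must be none, year or year_month")


@dataclass
class ModelFit:
    spec: ModelSpec
    coefficients: pd.Series  # log-scale beta, indexed by column name
    covariance: pd.DataFrame
    alpha: float  # gamma dispersion (Var = alpha mu^2)
    fitted_means: np.ndarray
    log_likelihood: float
    aicc: float
    n_obs: int
    converged: bool
    dropped_columns: tuple[str, ...]
    factor_levels: dict[str, list]
    grid: pd.DataFrame  # observed distinct combinations of model factors

    @property
    def n_params(self) -> int:
        """beta plus the dispersion alpha."""
        return len(self.coefficients) + 1


def _dummy_name(factor: str, level) -> str:
    return f"{factor}[{level}]"


def _build_design(
    data: pd.DataFrame, factors: Sequence[str], reference_levels: dict
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Treatment-coded design matrix with intercept.  Reference level per
    factor defaults to the first sorted observed level."""
    cols = {"Intercept": np.ones(len(data))}
    factor_levels: dict[str, list] = {}
    for f in factors:
        levels = sorted(data[f].unique(), key=str)
        ref = reference_levels.get(f, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {f!r}")
        levels = [ref] + [l for l in levels if l != ref]
        factor_levels[f] = levels
        for level in levels[1:]:
            cols[_dummy_name(f, level)] = (data[f] == level).to_numpy(float)
    return pd.DataFrame(cols, index=data.index), factor_levels


def _drop_aliased(x: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop columns that are linearly dependent on earlier ones (pivoted
    QR), mirroring how unsampled design cells make interactions or blocks
    aliased."""
    a = x.to_numpy(float)
    _, r, piv = scipy.linalg.qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(a.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep_idx = sorted(piv[:rank])
    dropped = tuple(x.columns[i] for i in sorted(set(range(a.shape[1])) - set(keep_idx)))
    return x.iloc[:, keep_idx], dropped


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Log-likelihood of gamma observations with mean mu, dispersion alpha
    (shape 1/alpha, scale mu*alpha)."""
    k = 1.0 / alpha
    return float(
        np.sum(
            k * np.log(k)
            - k * np.log(mu)
            - scipy.special.gammaln(k)
            + (k - 1.0) * np.log(y)
            - k * y / mu
        )
    )


def _ml_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximize the gamma log-likelihood over the dispersion alpha for
    fixed fitted means."""
    res = scipy.optimize.minimize_scalar(
        lambda la: -_gamma_loglik(y, mu, math.exp(la)),
        bounds=(-12.0, 8.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(math.exp(res.x))


def aicc_value(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """AICc = -2 ln L + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    if n_obs <= n_params + 1:
        raise ValueError(f"AICc undefined: n={n_obs} <= k+1={n_params + 1}")
    return (
        -2.0 * log_likelihood
        + 2.0 * n_params
        + 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    )


def fit_gamma_loglink(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood gamma regression with log link.

    Blocking dummies (year, or year and month-within-year) are appended to
    the fixed factors; aliased columns are dropped with a note in
    ``dropped_columns``.
    """
    y = data[spec.response].to_numpy(float)
    if not (y > 0).all():
        bad = data.index[data[spec.response] <= 0].tolist()
        raise ValueError(f"response must be strictly positive; offending rows {bad[:10]}")
    factors = list(spec.factors)
    block_factors: list[str] = []
    work = data.copy()
    if spec.blocking in ("year", "year_month"):
        work["year_block"] = work["year"].astype(str)
        block_factors.append("year_block")
    if spec.blocking == "year_month":
        work["year_month_block"] = (
            work["year"].astype(str) + ":" + work["month"].astype(str)
        )
        block_factors.append("year_month_block")
    x, factor_levels = _build_design(
        work, factors + block_factors, spec.reference_levels
    )
    x, dropped = _drop_aliased(x)

    model = sm.GLM(y, x.to_numpy(), family=sm.families.Gamma(sm.families.links.Log()))
    res = model.fit(tol=1e-12, maxiter=300)
    beta = pd.Series(res.params, index=x.columns)
    mu = np.exp(x.to_numpy() @ beta.to_numpy())
    alpha = _ml_alpha(y, mu)
    # Fisher information for beta under gamma/log-link has unit working
    # weights: cov(beta) = alpha * (X'X)^{-1}.
    xtx_inv = np.linalg.pinv(x.to_numpy().T @ x.to_numpy())
    cov = pd.DataFrame(alpha * xtx_inv, index=x.columns, columns=x.columns)
    ll = _gamma_loglik(y, mu, alpha)
    n, kparams = len(y), len(beta) + 1
    aicc_val = aicc_value(ll, kparams, n)
    grid = work[factors + block_factors].drop_duplicates().reset_index(drop=True)
    return ModelFit(
        spec=spec,
        coefficients=beta,
        covariance=cov,
        alpha=alpha,
        fitted_means=mu,
        log_likelihood=ll,
        aicc=aicc_val,
        n_obs=n,
        converged=bool(res.converged),
        dropped_columns=dropped,
        factor_levels=factor_levels,
        grid=grid,
    )


def aicc(fit: ModelFit) -> float:
    """Corrected Akaike information criterion:
    -2 ln L + 2k + 2k(k+1)/(n-k-1), k counting beta and alpha."""
    return fit.aicc


@dataclass
class EmmResult:
    factor: str
    table: pd.DataFrame  # level, emm (link), se, lower/upper (link), response scale

    def emm(self, level) -> float:
        return float(self.table.set_index("level").loc[level, "emm"])


def _row_vector(fit: ModelFit, assignment: dict) -> np.ndarray:
    """Design row for one cell of the reference grid, in the fitted
    (post-drop) column order."""
    vec = np.zeros(len(fit.coefficients))
    for i, name in enumerate(fit.coefficients.index):
        if name == "Intercept":
            vec[i] = 1.0
        else:
            f, level = name[:-1].split("[", 1)
            lev = assignment[f]
            vec[i] = 1.0 if str(lev) == level else 0.0
    return vec


def estimated_marginal_means(fit: ModelFit, factor: str) -> EmmResult:
    """Marginal mean of the linear predictor per level of ``factor``,
    averaged with equal weight over the observed distinct combinations of
    every other factor in the model (never-observed cells are absent from
    the grid and carry no weight)."""
    if factor not in fit.factor_levels:
        raise ValueError(f"{factor!r} is not a factor of the fitted model")
    others = [f for f in fit.factor_levels if f != factor]
    other_grid = (
        fit.grid[others].drop_duplicates().reset_index(drop=True)
        if others
        else pd.DataFrame([{}])
    )
    beta = fit.coefficients.to_numpy()
    cov = fit.covariance.to_numpy()
    observed_levels = set(fit.grid[factor]) if factor in fit.grid else set(
        fit.factor_levels[factor]
    )
    rows = []
    for level in fit.factor_levels[factor]:
        if level not in observed_levels:
            rows.append(
                {"level": level, "emm": np.nan, "se": np.nan, "estimable": False}
            )
            continue
        ls = np.zeros(len(beta))
        for _, combo in other_grid.iterrows():
            assignment = {factor: level, **combo.to_dict()}
            ls += _row_vector(fit, assignment)
        ls /= len(other_grid)
        est = float(ls @ beta)
        se = float(math.sqrt(ls @ cov @ ls))
        rows.append(
            {"level": level, "emm": est, "se": se, "estimable": True, "_L": ls}
        )
    table = pd.DataFrame(rows)
    table["lower"] = table["emm"] - Z_95 * table["se"]
    table["upper"] = table["emm"] + Z_95 * table["se"]
    table["response_emm"] = np.exp(table["emm"])
    table["response_lower"] = np.exp(table["lower"])
    table["response_upper"] = np.exp(table["upper"])
    return EmmResult(factor=factor, table=table)


def link_scale_sigma(alpha: float) -> float:
    """Population SD on the link (log) scale for a gamma variate with
    dispersion alpha: sqrt(trigamma(1/alpha)) = SD of log(x)."""
    return float(math.sqrt(scipy.special.polygamma(1, 1.0 / alpha)))


def pairwise_comparisons(
    emm: EmmResult, fit: ModelFit, sigma_pop: float | None = None
) -> pd.DataFrame:
    """All level pairs of the EMM factor: link-scale difference, Wald 95%
    CI, and Cohen's d = difference / sigma_pop.

    ``sigma_pop`` defaults to the model's link-scale residual SD
    (:func:`link_scale_sigma`).  A pair is flagged when the d CI excludes
    zero.  Non-estimable levels are skipped.
    """
    if sigma_pop is None:
        sigma_pop = link_scale_sigma(fit.alpha)
    table = emm.table[emm.table["estimable"]]
    cov = fit.covariance.to_numpy()
    rows = []
    recs = table.to_dict("records")
    for a, b in itertools.combinations(recs, 2):
        lvec = a["_L"] - b["_L"]
        diff = float(lvec @ fit.coefficients.to_numpy())
        se = float(math.sqrt(lvec @ cov @ lvec))
        lo, hi = diff - Z_95 * se, diff + Z_95 * se
        d = diff / sigma_pop
        rows.append(
            {
                "level_a": a["level"],
                "level_b": b["level"],
                "difference": diff,
                "se": se,
                "lower": lo,
                "upper": hi,
                "cohens_d": d,
                "d_lower": lo / sigma_pop,
                "d_upper": hi / sigma_pop,
                "flagged": (lo > 0) or (hi < 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "level_a",
            "level_b",
            "difference",
            "se",
            "lower",
            "upper",
            "cohens_d",
            "d_lower",
            "d_upper",
            "flagged",
        ],
    )
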