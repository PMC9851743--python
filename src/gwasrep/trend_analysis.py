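"""Temporal trend and group-difference tests for yearly proportions.

Three complementary views of a time trend are provided, matching
standard practice for yearly binomial shares:

* Cochran–Armitage test for trend on yearly success/total counts with
  linear year scores (calendar year minus window start), two-sided p
  from the normal reference;
* simple linear (OLS) regression of the yearly proportion on year —
  the headline estimator, reported as percentage points per year with
  a 95% t-based confidence interval;
* beta regression (logit link, constant precision, maximum likelihood)
  as a sensitivity analysis, reported as the average marginal effect in
  percentage points per year with a delta-method confidence interval.

A chi-square homogeneity test compares label distributions (e.g.
gender) across groups.  The final partial calendar year is excluded
from every trend window before testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.base.model import GenericLikelihoodModel
import statsmodels.api as sm

from .errors import ConvergenceError, InsufficientDataError

__all__ = [
    "YearlySeries",
    "TrendResult",
    "cochran_armitage_trend",
    "ols_trend",
    "beta_regression_trend",
    "chi_square_homogeneity",
]


@dataclass
class YearlySeries:
    """One observation per calendar year: counts and/or a proportion.

    ``successes``/``totals`` feed the count-based tests; ``proportions``
    (with ``basis``, e.g. number of papers) feed the regressions.  When
    only counts are given the proportion is the yearly success rate.
    """

    years: list[int]
    successes: list[int] | None = None
    totals: list[int] | None = None
    proportions: list[float] | None = None
    basis: list[int] | None = None

    def __post_init__(self):
        if self.proportions is None:
            if self.successes is None or self.totals is None:
                raise ValueError("need counts or proportions")
            for s, t in zip(self.successes, self.totals):
                if s > t:
                    raise ValueError("successes exceed total")
            self.proportions = [
                s / t if t else float("nan")
                for s, t in zip(self.successes, self.totals)
            ]
            self.basis = list(self.totals)

    @classmethod
    def from_counts(cls, by_year: dict[int, tuple[int, int]]) -> "YearlySeries":
        years = sorted(by_year)
        return cls(
            years,
            successes=[by_year[y][0] for y in years],
            totals=[by_year[y][1] for y in years],
        )

    @classmethod
    def from_proportions(cls, by_year: dict[int, tuple[float, int]]
                         ) -> "YearlySeries":
        years = sorted(by_year)
        return cls(
            years,
            proportions=[by_year[y][0] for y in years],
            basis=[by_year[y][1] for y in years],
        )

    def exclude_year(self, year: int) -> "YearlySeries":
        """Drop one year (e.g. the final, partially elapsed one)."""
        keep = [i for i, y in enumerate(self.years) if y != year]

        def take(xs):
            return [xs[i] for i in keep] if xs is not None else None

        return YearlySeries(
            [self.years[i] for i in keep],
            take(self.successes), take(self.totals),
            take(self.proportions), take(self.basis),
        )


@dataclass
class TrendResult:
    method: str
    statistic: float
    p_value: float
    slope_pp_per_year: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_years: int = 0
    df: int | None = None
    link_slope: float = float("nan")  # beta regression only (logit scale)
    link_slope_se: float = float("nan")
    warnings: list[str] = field(default_factory=list)


def cochran_armitage_trend(series: YearlySeries,
                           scores: list[float] | None = None) -> TrendResult:
    """Cochran–Armitage trend test on yearly success/total counts.

    The statistic is the standardised score covariance
    z = T / sqrt(Var T) with T = sum_i s_i (x_i - n_i pbar); its sign
    follows the trend direction.  Degenerate inputs (pooled proportion
    0 or 1, or constant scores) give statistic 0 with a boundary
    warning.
    """
    if series.successes is None or series.totals is None:
        raise InsufficientDataError("Cochran-Armitage needs yearly counts")
    years = [y for y, t in zip(series.years, series.totals) if t > 0]
    x = np.array(
        [s for s, t in zip(series.successes, series.totals) if t > 0],
        dtype=float,
    )
    n = np.array([t for t in series.totals if t > 0], dtype=float)
    if len(years) < 2:
        raise InsufficientDataError("need >= 2 years with observations")
    if scores is None:
        start = min(years)
        s = np.array([y - start for y in years], dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
    N = n.sum()
    pbar = x.sum() / N
    t_stat = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / N)
    warns = []
    if var <= 0:
        warns.append("degenerate series (boundary pooled proportion)")
        z = 0.0
    else:
        z = t_stat / math.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return TrendResult(
        "cochran_armitage", z, float(p), n_years=len(years), warnings=warns
    )


def ols_trend(series: YearlySeries, weighted: bool = False) -> TrendResult:
    """Least-squares slope of yearly proportion on year, in pp/year.

    Unweighted by default (each year one point); ``weighted=True``
    weights years by their basis (paper or sample counts).
    """
    y = np.asarray(series.proportions, dtype=float)
    t = np.asarray(series.years, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 years for regression")
    X = sm.add_constant(t)
    if weighted:
        model = sm.WLS(y, X, weights=np.asarray(series.basis, dtype=float))
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    slope = res.params[1]
    ci = res.conf_int(alpha=0.05)[1]
    # guard the zero-residual exact-line case where the t reference is 0/0
    p = float(res.pvalues[1]) if not math.isnan(res.pvalues[1]) else 0.0
    return TrendResult(
        "ols", float(res.tvalues[1]), p,
        slope_pp_per_year=float(slope * 100.0),
        ci_low=float(ci[0] * 100.0), ci_high=float(ci[1] * 100.0),
        n_years=len(t), df=int(res.df_resid),
    )


class _BetaReg(GenericLikelihoodModel):
    """Beta regression with logit mean link and constant precision."""

    def __init__(self, endog, exog, **kwargs):
        super().__init__(endog, exog, **kwargs)
        # params: [beta_0, beta_1, ..., log(phi)]
        self.df_model = exog.shape[1]
        self.df_resid = len(endog) - exog.shape[1] - 1

    def loglike(self, params):
        beta = params[:-1]
        phi = math.exp(params[-1])
        eta = self.exog @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        y = self.endog
        from scipy.special import gammaln
        ll = (
            gammaln(phi) - gammaln(mu * phi) - gammaln((1 - mu) * phi)
            + (mu * phi - 1) * np.log(y)
            + ((1 - mu) * phi - 1) * np.log(1 - y)
        )
        return np.sum(ll)


def _squeeze_boundary(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Open-interval transform (y*(n-1)+0.5)/n when 0/1 values occur."""
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        n = len(y)
        return (y * (n - 1) + 0.5) / n, True
    return y, False


def beta_regression_trend(series: YearlySeries) -> TrendResult:
    """Beta regression of yearly proportion on year.

    Reports the average marginal effect d mu / d year, averaged over
    observed years and converted to percentage points per year, with a
    delta-method 95% CI; the logit-scale slope and its SE are also
    carried for calibration checks.
    """
    y = np.asarray(series.proportions, dtype=float)
    t = np.asarray(series.years, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 years for regression")
    y, squeezed = _squeeze_boundary(y)
    tc = t - t.mean()  # centering stabilises the optimiser only
    X = np.column_stack([np.ones_like(tc), tc])

    # moment-based start values via the logit-OLS fit
    eta0 = np.log(y / (1 - y))
    b_start = np.linalg.lstsq(X, eta0, rcond=None)[0]
    mu0 = float(np.mean(y))
    phi_start = max(mu0 * (1 - mu0) / max(np.var(y), 1e-6) - 1, 2.0)
    start = np.array([b_start[0], b_start[1], math.log(phi_start)])

    model = _BetaReg(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, method="bfgs", maxiter=500,
                        disp=0)
        if not res.mle_retvals.get("converged", False):
            # polish a rough Nelder-Mead solution with BFGS for the Hessian
            rough = model.fit(start_params=start, method="nm",
                              maxiter=2000, disp=0)
            res = model.fit(start_params=rough.params, method="bfgs",
                            maxiter=500, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "beta regression failed to converge", trace=res.mle_retvals
        )
    b0, b1 = res.params[0], res.params[1]
    cov = res.cov_params()[:2, :2]
    eta = b0 + b1 * tc
    mu = 1.0 / (1.0 + np.exp(-eta))
    dmu = mu * (1 - mu)
    ame = float(np.mean(b1 * dmu))
    # delta method: gradient of AME wrt (b0, b1)
    g0 = float(np.mean(b1 * (1 - 2 * mu) * dmu))
    g1 = float(np.mean(dmu + b1 * (1 - 2 * mu) * dmu * tc))
    g = np.array([g0, g1])
    ame_var = float(g @ cov @ g)
    ame_se = math.sqrt(max(ame_var, 0.0))
    se1 = math.sqrt(max(float(cov[1, 1]), 0.0))
    zstat = b1 / se1 if se1 > 0 else float("inf") * np.sign(b1)
    p = 2 * sps.norm.sf(abs(zstat))
    result = TrendResult(
        "beta_regression", float(zstat), float(p),
        slope_pp_per_year=ame * 100.0,
        ci_low=(ame - 1.959963984540054 * ame_se) * 100.0,
        ci_high=(ame + 1.959963984540054 * ame_se) * 100.0,
        n_years=len(t),
        link_slope=float(b1), link_slope_se=se1,
    )
    if squeezed:
        result.warnings.append("boundary proportions squeezed into (0,1)")
    return result


def yearly_attribute_series(pubs, attribute: str, author_category: str,
                            target: str, income=None) -> YearlySeries:
    """Per-paper-weighted yearly share of one category of an attribute.

    Each year's point is the mean, over that year's papers, of the
    paper's fraction for ``target`` (e.g. country='United States' or
    gender='women'); the basis is the number of contributing papers.
    """
    from .errors import EmptyTableError
    from .representation_stats import paper_attribute_proportions

    by_year: dict[int, list[float]] = {}
    for pub in pubs:
        try:
            pm = paper_attribute_proportions(
                pub, attribute, author_category, income
            )
        except EmptyTableError:
            continue
        by_year.setdefault(pub.year, []).append(pm.get(target, 0.0))
    data = {
        y: (sum(fracs) / len(fracs), len(fracs))
        for y, fracs in by_year.items()
    }
    return YearlySeries.from_proportions(data)


def yearly_gender_counts(pubs, author_category: str,
                         label: str = "women") -> YearlySeries:
    """Pooled yearly (label, men+women) author counts for count tests."""
    from .catalog_io import assign_author_positions

    by_year: dict[int, tuple[int, int]] = {}
    for pub in pubs:
        s, t = by_year.get(pub.year, (0, 0))
        for a in assign_author_positions(pub)[author_category]:
            if a.gender not in ("men", "women"):
                continue
            t += 1
            if a.gender == label:
                s += 1
        by_year[pub.year] = (s, t)
    by_year = {y: st for y, st in by_year.items() if st[1] > 0}
    return YearlySeries.from_counts(by_year)


def yearly_participant_series(entries_by_year: dict, target: str,
                              kind: str = "recruitment_country"
                              ) -> YearlySeries:
    """Yearly sample-weighted share of one recruitment country or ancestry."""
    from .errors import EmptyTableError
    from .representation_stats import (
        ancestry_proportions, recruitment_proportions,
    )

    fn = recruitment_proportions if kind == "recruitment_country" else \
        ancestry_proportions
    data = {}
    for year in sorted(entries_by_year):
        try:
            table, _ = fn(entries_by_year[year], "all_traits")
        except EmptyTableError:
            continue
        data[year] = (table.proportions.get(target, 0.0), table.n_basis)
    return YearlySeries.from_proportions(data)


def chi_square_homogeneity(table) -> TrendResult:
    """Pearson chi-square test comparing distributions across k groups.

    ``table`` is a 2 x k (or r x k) count array; no continuity
    correction.  A warning is attached when any expected cell is < 1.
    """
    arr = np.asarray(table, dtype=float)
    if np.any(arr.sum(axis=0) <= 0):
        raise InsufficientDataError("every column needs a positive total")
    chi2, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    warns = []
    if np.any(expected < 1):
        warns.append("expected cell count below 1")
    return TrendResult(
        "chi_square", float(chi2), float(p), df=int(dof),
        n_years=arr.shape[1], warnings=warns,
    )
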