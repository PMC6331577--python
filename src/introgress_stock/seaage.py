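"""Multinomial-logit mixed model for sea age (1, 2, 3+ sea winters).

For individuals k born in year j (within one sex), the two log-odds
contrasts against the 3+ baseline are

    ln Pr(y=1)/Pr(y=3+) = a1 + b1 D_jk + d1 (Dbar_j - Dbar) + t1_j,
    ln Pr(y=2)/Pr(y=3+) = a2 + b2 D_jk + d2 (Dbar_j - Dbar) + t2_j,

where D is the individual's proportion farmed ancestry, Dbar_j the birth-
year mean, Dbar the grand mean of year means (so b is the within-year
effect and d the difference between within- and among-year effects), and
t1_j, t2_j independent normal year effects on the logit scale.

The marginal likelihood integrates the bivariate year effect per birth year
by a Laplace approximation: the joint mode is found with damped Newton
steps (closed-form 2x2 solves, vectorised over years) and the Gaussian
curvature correction applied at the mode.  An adaptive Gauss-Hermite
cross-check of the same integral is provided for validation.  Support for
an introgression effect is assessed by the likelihood-ratio statistic
between the full model and the one with b1 = b2 = 0 (chi-square, 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = ["SeaAgeFit", "fit_sea_age_model", "sea_age_likelihood_ratio", "category_probabilities"]

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-3), np.log(20.0)


@dataclass
class SeaAgeFit:
    """Fitted parameter blocks of the sea-age model for one sex."""

    a: tuple
    b: tuple
    d: tuple
    sd_t: tuple
    loglik: float
    converged: bool
    nobs: int
    n_params: int
    include_b: bool = True
    include_d: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _prepare(table: pd.DataFrame, intro_col: str, year_col: str, age_col: str):
    age_raw = table[age_col]
    age = np.array([3 if str(a) in ("3+", "3") or (isinstance(a, (int, float)) and a >= 3) else int(a)
                    for a in age_raw])
    if not set(np.unique(age)) <= {1, 2, 3}:
        raise ValueError("sea ages must fall in {1, 2, 3+}")
    for cat in (1, 2, 3):
        if not (age == cat).any():
            raise ValueError(f"sea-age category {cat if cat < 3 else '3+'} absent from the data")
    years, year_idx = np.unique(table[year_col].to_numpy(), return_inverse=True)
    d = table[intro_col].to_numpy(dtype=float)
    year_mean = np.array([d[year_idx == j].mean() for j in range(len(years))])
    grand = year_mean.mean()
    x_year = year_mean - grand  # the (Dbar_j - Dbar) covariate
    y1 = (age == 1).astype(float)
    y2 = (age == 2).astype(float)
    return d, year_idx, len(years), x_year, y1, y2


def _laplace_nll(theta, d, year_idx, n_years, x_year, y1, y2, fix_sd_zero):
    a1, b1, d1, a2, b2, d2 = theta[:6]
    eta1_fix = a1 + b1 * d + d1 * x_year[year_idx]
    eta2_fix = a2 + b2 * d + d2 * x_year[year_idx]
    n1 = np.bincount(year_idx, weights=y1, minlength=n_years)
    n2 = np.bincount(year_idx, weights=y2, minlength=n_years)

    def obj_parts(t1, t2):
        e1 = eta1_fix + t1[year_idx]
        e2 = eta2_fix + t2[year_idx]
        m = np.maximum(0.0, np.maximum(e1, e2))
        lse = m + np.log(np.exp(-m) + np.exp(e1 - m) + np.exp(e2 - m))
        ll_i = y1 * e1 + y2 * e2 - lse
        p1 = np.exp(e1 - lse)
        p2 = np.exp(e2 - lse)
        return ll_i, p1, p2

    if fix_sd_zero:
        ll_i, _, _ = obj_parts(np.zeros(n_years), np.zeros(n_years))
        return -float(ll_i.sum())

    sd1, sd2 = np.exp(theta[6]), np.exp(theta[7])
    prec1, prec2 = 1.0 / sd1**2, 1.0 / sd2**2
    t1 = np.zeros(n_years)
    t2 = np.zeros(n_years)

    def joint(t1, t2):
        ll_i, p1, p2 = obj_parts(t1, t2)
        pen = 0.5 * (prec1 * t1**2 + prec2 * t2**2)
        per_year = np.bincount(year_idx, weights=ll_i, minlength=n_years) - pen
        return per_year, p1, p2

    per_year, p1, p2 = joint(t1, t2)
    for _ in range(100):
        s1 = np.bincount(year_idx, weights=p1, minlength=n_years)
        s2 = np.bincount(year_idx, weights=p2, minlength=n_years)
        g1 = n1 - s1 - prec1 * t1
        g2 = n2 - s2 - prec2 * t2
        if max(np.abs(g1).max(), np.abs(g2).max()) < 1e-9:
            break
        v11 = np.bincount(year_idx, weights=p1 * (1 - p1), minlength=n_years) + prec1
        v22 = np.bincount(year_idx, weights=p2 * (1 - p2), minlength=n_years) + prec2
        v12 = -np.bincount(year_idx, weights=p1 * p2, minlength=n_years)
        det = v11 * v22 - v12**2
        dt1 = (v22 * g1 - v12 * g2) / det
        dt2 = (v11 * g2 - v12 * g1) / det
        step = 1.0
        for _ in range(25):  # damped steps: never accept a decrease
            nt1, nt2 = t1 + step * dt1, t2 + step * dt2
            new_per_year, np1, np2 = joint(nt1, nt2)
            if new_per_year.sum() >= per_year.sum() - 1e-12:
                t1, t2, per_year, p1, p2 = nt1, nt2, new_per_year, np1, np2
                break
            step *= 0.5

    v11 = np.bincount(year_idx, weights=p1 * (1 - p1), minlength=n_years) + prec1
    v22 = np.bincount(year_idx, weights=p2 * (1 - p2), minlength=n_years) + prec2
    v12 = -np.bincount(year_idx, weights=p1 * p2, minlength=n_years)
    logdet = np.log(v11 * v22 - v12**2)
    ll = per_year.sum() - n_years * np.log(sd1 * sd2) - 0.5 * logdet.sum()
    return -float(ll)


def _pack_mask(include_b: bool, include_d: bool, fix_sd_zero: bool):
    # theta layout: a1 b1 d1 a2 b2 d2 log_sd1 log_sd2
    free = np.ones(8, dtype=bool)
    if not include_b:
        free[[1, 4]] = False
    if not include_d:
        free[[2, 5]] = False
    if fix_sd_zero:
        free[[6, 7]] = False
    return free


def fit_sea_age_model(
    table: pd.DataFrame,
    sex: Optional[str] = None,
    intro_col: str = "introgression",
    year_col: str = "brood_year",
    age_col: str = "sea_age",
    include_b: bool = True,
    include_d: bool = True,
    fix_sd_zero: bool = False,
) -> SeaAgeFit:
    """Maximise the Laplace-approximated marginal likelihood for one sex.

    ``fix_sd_zero`` drops the year random effects entirely, reducing the
    model to a fixed-effects multinomial logit (useful as an oracle check).
    ``include_b=False`` fits the reduced model with b1 = b2 = 0 used by the
    likelihood-ratio test for an introgression effect.
    """
    if sex is not None:
        table = table[table["sex"] == sex]
        if table.empty:
            raise ValueError(f"no rows for sex {sex!r}")
    d, year_idx, n_years, x_year, y1, y2 = _prepare(table, intro_col, year_col, age_col)
    n = len(d)

    n1, n2 = y1.sum(), y2.sum()
    n3 = max(n - n1 - n2, 1.0)
    theta0 = np.array([
        np.log(max(n1, 1.0) / n3), 0.0, 0.0,
        np.log(max(n2, 1.0) / n3), 0.0, 0.0,
        np.log(0.25), np.log(0.25),
    ])
    free = _pack_mask(include_b, include_d, fix_sd_zero)

    def unpack(x):
        full = np.zeros(8)  # excluded b/d terms stay pinned at zero
        full[free] = x
        full[[6, 7]] = np.clip(full[[6, 7]], _LOG_SD_MIN, _LOG_SD_MAX)
        return full

    x0 = theta0[free]
    res = minimize(
        lambda x: _laplace_nll(unpack(x), d, year_idx, n_years, x_year, y1, y2, fix_sd_zero),
        x0,
        method="L-BFGS-B",
    )
    theta = unpack(res.x)
    a = (float(theta[0]), float(theta[3]))
    b = (float(theta[1]) if include_b else 0.0, float(theta[4]) if include_b else 0.0)
    dd = (float(theta[2]) if include_d else 0.0, float(theta[5]) if include_d else 0.0)
    sd = (0.0, 0.0) if fix_sd_zero else tuple(
        float(np.exp(np.clip(v, _LOG_SD_MIN, _LOG_SD_MAX))) for v in theta[[6, 7]]
    )
    return SeaAgeFit(
        a=a, b=b, d=dd, sd_t=sd,
        loglik=-float(res.fun),
        converged=bool(res.success),
        nobs=n,
        n_params=int(free.sum()),
        include_b=include_b,
        include_d=include_d,
    )


def sea_age_likelihood_ratio(
    table: pd.DataFrame,
    sex: Optional[str] = None,
    include_d: bool = True,
    **kwargs,
) -> tuple[float, float, SeaAgeFit, SeaAgeFit]:
    """Twice the log-likelihood difference between the full model and the
    b1 = b2 = 0 reduction, with its chi-square (2 df) p-value."""
    full = fit_sea_age_model(table, sex=sex, include_b=True, include_d=include_d, **kwargs)
    reduced = fit_sea_age_model(table, sex=sex, include_b=False, include_d=include_d, **kwargs)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    pval = float(chi2.sf(stat, df=2))
    return stat, pval, full, reduced


def category_probabilities(fit: SeaAgeFit, d: np.ndarray, x_year: float = 0.0,
                           t1: float = 0.0, t2: float = 0.0) -> np.ndarray:
    """Implied (P(1SW), P(2SW), P(3+)) for individuals with ancestry ``d``."""
    d = np.asarray(d, dtype=float)
    e1 = fit.a[0] + fit.b[0] * d + fit.d[0] * x_year + t1
    e2 = fit.a[1] + fit.b[1] * d + fit.d[1] * x_year + t2
    denom = 1.0 + np.exp(e1) + np.exp(e2)
    return np.c_[np.exp(e1) / denom, np.exp(e2) / denom, 1.0 / denom]


def gauss_hermite_marginal_loglik(
    fit: SeaAgeFit,
    table: pd.DataFrame,
    sex: Optional[str] = None,
    intro_col: str = "introgression",
    year_col: str = "brood_year",
    age_col: str = "sea_age",
    order: int = 21,
) -> float:
    """Adaptive Gauss-Hermite evaluation of the marginal log-likelihood at a
    fitted parameter vector — an independent check of the Laplace value."""
    if sex is not None:
        table = table[table["sex"] == sex]
    d, year_idx, n_years, x_year, y1, y2 = _prepare(table, intro_col, year_col, age_col)
    sd1, sd2 = (max(s, 1e-8) for s in fit.sd_t)
    nodes, weights = np.polynomial.hermite_e.hermegauss(order)  # probabilists' weights

    total = 0.0
    for j in range(n_years):
        idx = year_idx == j
        e1f = fit.a[0] + fit.b[0] * d[idx] + fit.d[0] * x_year[j]
        e2f = fit.a[1] + fit.b[1] * d[idx] + fit.d[1] * x_year[j]
        vals = np.empty((order, order))
        for p, t1 in enumerate(nodes * sd1):
            e1 = e1f + t1
            for q, t2 in enumerate(nodes * sd2):
                e2 = e2f + t2
                m = np.maximum(0.0, np.maximum(e1, e2))
                lse = m + np.log(np.exp(-m) + np.exp(e1 - m) + np.exp(e2 - m))
                vals[p, q] = float((y1[idx] * e1 + y2[idx] * e2 - lse).sum())
        w2 = np.add.outer(np.log(weights), np.log(weights)) + vals
        mx = w2.max()
        total += mx + np.log(np.exp(w2 - mx).sum()) - np.log(2 * np.pi)
    return float(total)
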