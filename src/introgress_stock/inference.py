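"""Mixed-model suite for reproductive success, eggs, growth and introgression.

All linear mixed models have a single random intercept (brood year or run
year) and are fitted by maximum likelihood — not REML — so AIC comparisons
across fixed-effect structures are coherent.  The AIC parameter count
includes the random-intercept and residual variances.  When a model's
random grouping has fewer than two levels, or the variance estimate
collapses to the boundary, the fit degrades to ordinary least squares
(exact ML at a zero variance component).

The run-year introgression contrast is the overdispersed logit model

    logit(P_ind,ij) = a_i + b_i H_ij + e_ij,

with year i, individual j, H = 1 for hatchery-reared fish and e an i.i.d.
normal observation-level effect absorbing extra-binomial variation.  Its ML
fit is closed-form (cell means on the logit scale with a pooled residual
variance).  Confidence intervals throughout are Wald: estimate +/- 1.96 SE,
transformed to the factor or percent scale afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .seaage import SeaAgeFit, fit_sea_age_model, sea_age_likelihood_ratio  # noqa: F401

__all__ = [
    "ModelSpec",
    "ModelFit",
    "IntrogressionContrastFit",
    "fit_lmm",
    "select_by_aic",
    "fit_count_model_suite",
    "fit_egg_models",
    "fit_smolt_length_model",
    "fit_introgression_glmm",
    "wald_ci_transform",
    "SeaAgeFit",
    "fit_sea_age_model",
    "sea_age_likelihood_ratio",
    "reproduce_reported_delta_aic",
]

Z_95 = 1.96  # the conventional 95% normal quantile used for all intervals


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, random grouping."""

    response: str
    terms: tuple
    group: Optional[str] = "brood_year"
    log_response: bool = True
    label: str = ""

    @property
    def formula(self) -> str:
        lhs = f"np.log({self.response})" if self.log_response else self.response
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{lhs} ~ {rhs}"

    def columns(self) -> list[str]:
        cols = [self.response]
        if self.group:
            cols.append(self.group)
        return cols


@dataclass
class ModelFit:
    """Coefficients, variances and fit statistics of one fitted model."""

    label: str
    coef_names: list
    coef: np.ndarray
    se: np.ndarray
    re_var: Optional[float]
    resid_var: float
    loglik: float
    n_params: int
    nobs: int
    converged: bool
    spec: Optional[ModelSpec] = None
    delta_aic: Optional[float] = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def coefficient(self, name: str) -> tuple[float, float]:
        i = self.coef_names.index(name)
        return float(self.coef[i]), float(self.se[i])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.coef_names, "estimate": self.coef, "se": self.se}
        ).assign(model=self.label, aic=self.aic)


def _check_design(spec: ModelSpec, data: pd.DataFrame) -> None:
    missing = [c for c in spec.columns() if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing required columns: {missing}")
    import patsy

    y, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased or 'unidentified'}")


def _ols_fit(spec: ModelSpec, data: pd.DataFrame, count_re: bool, converged=True) -> ModelFit:
    res = smf.ols(spec.formula, data).fit()
    n = int(res.nobs)
    # statsmodels OLS llf is the Gaussian ML log-likelihood (sigma^2 = SSR/n)
    k = len(res.params) + 1 + (1 if count_re else 0)
    return ModelFit(
        label=spec.label or spec.formula,
        coef_names=list(res.params.index),
        coef=res.params.to_numpy(),
        se=res.bse.to_numpy(),
        re_var=0.0 if count_re else None,
        resid_var=float(res.ssr / n),
        loglik=float(res.llf),
        n_params=k,
        nobs=n,
        converged=converged,
        spec=spec,
    )


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """ML fit of a linear mixed model with one random intercept.

    Degrades to a fixed-effects (OLS) fit with a warning when the grouping
    factor has fewer than two levels; a boundary variance estimate is
    reported as exactly zero with OLS coefficients (the ML solution there).
    """
    _check_design(spec, data)
    if spec.group is None or data[spec.group].nunique() < 2:
        if spec.group is not None:
            warnings.warn(
                f"grouping factor '{spec.group}' has <2 levels; fitting fixed effects only",
                stacklevel=2,
            )
        return _ols_fit(spec, data, count_re=False)

    model = smf.mixedlm(spec.formula, data, groups=data[spec.group])
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=False, method=method)
            except Exception:
                continue
            if res is None or (cand.converged and not res.converged):
                res = cand
            if res is not None and res.converged:
                break
    if res is None:
        raise RuntimeError(f"mixed-model optimisation failed for: {spec.formula}")

    re_var = float(np.asarray(res.cov_re)[0, 0])
    resid_var = float(res.scale)
    if not res.converged or re_var < 1e-8 * resid_var:
        # boundary: the ML fit is OLS with a zero variance component
        fit = _ols_fit(spec, data, count_re=True, converged=True)
        return fit

    fe = res.fe_params
    k = len(fe) + 2  # fixed effects + random-intercept variance + residual variance
    return ModelFit(
        label=spec.label or spec.formula,
        coef_names=list(fe.index),
        coef=fe.to_numpy(),
        se=res.bse_fe.to_numpy(),
        re_var=re_var,
        resid_var=resid_var,
        loglik=float(res.llf),
        n_params=k,
        nobs=int(res.nobs),
        converged=bool(res.converged),
        spec=spec,
    )


def select_by_aic(specs: Sequence[ModelSpec], data: pd.DataFrame) -> list[ModelFit]:
    """Fit every candidate by ML on the same observations; rank by AIC."""
    if len(specs) < 2:
        raise ValueError("model selection needs at least two candidates")
    needed = sorted({c for s in specs for c in s.columns()})
    if data[needed].isna().any().any():
        raise ValueError("candidates would be fitted on differing rows (missing values present)")
    fits = [fit_lmm(s, data) for s in specs]
    if len({f.nobs for f in fits}) != 1:
        raise ValueError("candidates were fitted on differing numbers of observations")
    fits.sort(key=lambda f: f.aic)
    best = fits[0].aic
    for f in fits:
        f.delta_aic = f.aic - best
    return fits


# ---------------------------------------------------------------------------
# the study's model suite


def _with_interactions(table: pd.DataFrame, intro_col: str = "pair_introgression") -> pd.DataFrame:
    out = table.copy()
    out["introgression_wild_dam"] = out[intro_col] * (1 - out["dam_hatchery"])
    out["introgression_hatchery_dam"] = out[intro_col] * out["dam_hatchery"]
    return out


def fit_count_model_suite(
    family_table: pd.DataFrame, intro_col: str = "pair_introgression"
) -> tuple[ModelFit, list[ModelFit]]:
    """The two reported recapture-count models, ranked by AIC.

    (i) dam background + background-specific introgression slopes;
    (ii) the same plus log egg number — the best model.  Response is the
    natural log of the per-pair count of offspring recaptured as adults
    (all >= 1 by construction of the family table); brood year is the
    random intercept.
    """
    data = _with_interactions(family_table, intro_col)
    base_terms = ("dam_hatchery", "introgression_wild_dam", "introgression_hatchery_dam")
    specs = [
        ModelSpec("n_offspring", base_terms, label="introgression + dam background"),
        ModelSpec(
            "n_offspring", base_terms + ("np.log(egg_number)",), label="best (+ log egg number)"
        ),
    ]
    ladder = select_by_aic(specs, data)
    return ladder[0], ladder


def fit_egg_models(
    dam_table: pd.DataFrame, intro_col: str = "dam_introgression"
) -> tuple[ModelFit, ModelFit]:
    """Best egg-size and egg-number models.

    Egg size: log egg size ~ dam background + log dam weight + background-
    specific introgression; egg number: log egg number ~ log dam weight +
    dam background.  Both with a brood-year random intercept.
    """
    data = dam_table.copy()
    data["introgression_wild_dam"] = data[intro_col] * (1 - data["dam_hatchery"])
    data["introgression_hatchery_dam"] = data[intro_col] * data["dam_hatchery"]
    size_fit = fit_lmm(
        ModelSpec(
            "egg_size_ml",
            ("dam_hatchery", "np.log(dam_weight_g)", "introgression_wild_dam",
             "introgression_hatchery_dam"),
            label="egg size",
        ),
        data,
    )
    number_fit = fit_lmm(
        ModelSpec("egg_number", ("np.log(dam_weight_g)", "dam_hatchery"), label="egg number"),
        data,
    )
    return size_fit, number_fit


def fit_smolt_length_model(
    adult_table: pd.DataFrame,
    intro_col: str = "introgression",
    length_col: str = "smolt_length_mm",
    mixed: bool = True,
) -> tuple[ModelFit, tuple[float, float, float]]:
    """Growth model: log back-calculated smolt length on introgression.

    Separate intercepts per sea-age category, a common introgression slope
    and a brood-year random intercept.  Returns the fit and the percent
    size difference at full introgression, 100*(exp(slope) - 1), with its
    Wald 95% interval on the percent scale.
    """
    terms = ("C(sea_age)", intro_col)
    spec = ModelSpec(length_col, terms, group="brood_year" if mixed else None,
                     label="smolt length")
    fit = fit_lmm(spec, adult_table)
    est, se = fit.coefficient(intro_col)
    pct = wald_ci_transform(est, se, "percent")
    return fit, pct


@dataclass
class IntrogressionContrastFit:
    """Per-run-year wild level and wild-vs-hatchery contrast on the logit scale."""

    years: np.ndarray
    a: np.ndarray                 # annual wild mean (logit)
    b: np.ndarray                 # annual hatchery - wild contrast (logit); NaN if untestable
    se_b: np.ndarray
    significant: np.ndarray       # Wald z-test of b_i = 0 at the given alpha
    testable: np.ndarray
    sigma2: float                 # observation-level (overdispersion) variance
    loglik: float
    grand_mean_wild: float        # back-transformed mean of a_i
    grand_mean_hatchery: float    # back-transformed mean of a_i + b_i
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_year": self.years,
                "a_wild_logit": self.a,
                "b_contrast_logit": self.b,
                "se_b": self.se_b,
                "significant": self.significant,
                "testable": self.testable,
            }
        )


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def fit_introgression_glmm(
    run_table: pd.DataFrame,
    p_col: str = "p_ind",
    alpha: float = 0.05,
    eps: float = 1e-6,
) -> IntrogressionContrastFit:
    """ML fit of the overdispersed logit model for run-year contrasts.

    Needs columns run_year, hatchery (0/1) and the per-individual farmed
    membership ``p_col`` in [0, 1] (boundary values nudged inward by
    ``eps``).  Years containing only one group get an untestable contrast.
    """
    data = run_table.copy()
    p = np.clip(data[p_col].to_numpy(dtype=float), eps, 1.0 - eps)
    data["_y"] = _logit(p)

    years = np.sort(data["run_year"].unique())
    a = np.full(len(years), np.nan)
    b = np.full(len(years), np.nan)
    se_b = np.full(len(years), np.nan)
    testable = np.zeros(len(years), dtype=bool)
    n0 = np.zeros(len(years)); n1 = np.zeros(len(years))
    ssr = 0.0
    n_total = 0
    n_params = 0
    hatchery_levels = []

    for i, yr in enumerate(years):
        sub = data[data["run_year"] == yr]
        g0 = sub[sub["hatchery"] == 0]["_y"].to_numpy()
        g1 = sub[sub["hatchery"] == 1]["_y"].to_numpy()
        n0[i], n1[i] = len(g0), len(g1)
        n_total += len(sub)
        if len(g0) and len(g1):
            a[i] = g0.mean()
            b[i] = g1.mean() - g0.mean()
            ssr += ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
            n_params += 2
            testable[i] = True
            hatchery_levels.append(a[i] + b[i])
        elif len(g0):
            a[i] = g0.mean()
            ssr += ((g0 - g0.mean()) ** 2).sum()
            n_params += 1
        elif len(g1):
            hatchery_levels.append(g1.mean())
            ssr += ((g1 - g1.mean()) ** 2).sum()
            n_params += 1

    sigma2 = ssr / n_total  # ML estimate of the observation-level variance
    # degenerate (noise-free) samples have an unbounded Gaussian likelihood
    loglik = np.inf if sigma2 <= 0 else -0.5 * n_total * (np.log(2 * np.pi * sigma2) + 1.0)
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        se_b = np.where(testable, np.sqrt(sigma2 * (1.0 / n0 + 1.0 / n1)), np.nan)
        z = np.abs(b) / se_b
    significant = np.where(testable, z > norm.ppf(1 - alpha / 2.0), False).astype(bool)

    wild_levels = a[~np.isnan(a)]
    return IntrogressionContrastFit(
        years=years,
        a=a,
        b=b,
        se_b=se_b,
        significant=significant,
        testable=testable,
        sigma2=float(sigma2),
        loglik=float(loglik),
        grand_mean_wild=float(_expit(np.mean(wild_levels))) if len(wild_levels) else np.nan,
        grand_mean_hatchery=float(_expit(np.mean(hatchery_levels))) if hatchery_levels else np.nan,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Wald intervals


def wald_ci_transform(
    estimate: float, se: float, transform: str = "identity"
) -> tuple[float, float, float]:
    """95% Wald interval estimate +/- 1.96 SE, then transformed.

    Transforms: ``identity``; ``exp`` (factor scale); ``percent``
    (100*(exp(x) - 1), a percent size difference).
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    lo, hi = estimate - Z_95 * se, estimate + Z_95 * se
    if transform == "identity":
        f = lambda x: x
    elif transform == "exp":
        f = np.exp
    elif transform == "percent":
        f = lambda x: 100.0 * (np.exp(x) - 1.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return float(f(estimate)), float(f(lo)), float(f(hi))


# ---------------------------------------------------------------------------
# external archived data


def reproduce_reported_delta_aic(source_path: str) -> float:
    """Re-run the count-model comparison on the study's archived family table.

    Requires the externally archived source workbook (Dryad
    doi:10.5061/dryad.1nh877d, ``SourceData.xlsx``), which is not bundled:
    this quantity is only reproducible with that download.  The sheet must
    carry per-pair columns for the recapture count, pair introgression, dam
    background and egg number (named as in the archive or their obvious
    aliases below).
    """
    import os

    if not os.path.exists(source_path):
        raise FileNotFoundError(
            "archived source data not found at "
            f"{source_path!r}; this comparison requires the external Dryad "
            "archive (doi:10.5061/dryad.1nh877d, SourceData.xlsx) and cannot "
            "run offline"
        )
    raw = pd.read_excel(source_path)
    aliases = {
        "n_offspring": ["n_offspring", "offspring", "recaptures", "no_offspring", "N"],
        "pair_introgression": ["pair_introgression", "introgression", "D", "mean_introgression"],
        "dam_hatchery": ["dam_hatchery", "dam_background", "mother_hatchery"],
        "egg_number": ["egg_number", "n_eggs", "eggs", "number_of_eggs"],
        "brood_year": ["brood_year", "year", "cohort"],
    }
    cols = {}
    lower = {c.lower().strip(): c for c in raw.columns}
    for want, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                cols[want] = lower[name.lower()]
                break
        else:
            raise ValueError(f"could not locate a column for {want!r} in {source_path}")
    table = raw[[cols[k] for k in aliases]].copy()
    table.columns = list(aliases)
    _, ladder = fit_count_model_suite(table)
    return float(ladder[-1].delta_aic)
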