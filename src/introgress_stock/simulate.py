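"""Synthetic hatchery-supplementation studies with known ground truth.

The generator emulates the structure of a stocked Atlantic salmon river
study: a SNP reference panel with farm/wild-diagnostic loci, broodstock
pairs crossed over several brood years, Mendelian offspring genotypes with
genotyping error and dropout, egg production and scale-derived phenotypes,
and run-year samples of returning wild-born and hatchery-reared adults.

Every quantity that later serves as a regression target retains its
generating value, so parameter-recovery tests are well posed.  All
randomness flows from one top-level seed through named substreams
(:func:`introgress_stock._rng.substream`).

Default effect sizes are the study conditions the analysis is meant to
recover: the best count-model coefficients (intercept -4.5564, hatchery-dam
background 0.5560, wild-born-dam introgression 1.5145, hatchery-dam
introgression -0.5018, log egg number 0.7069), egg-size factors 0.86
(hatchery dam) and 0.67 (full introgression, wild-born dam), a 6.2% smolt
size effect of full introgression in hatchery-reared fish, broodstock
introgression means 0.113 (wild-born) / 0.303 (hatchery-reared) and
run-year adult means 0.092 / 0.27.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .ancestry import ReferencePanel, estimate_p_ind

__all__ = [
    "PanelSpec",
    "EffectConfig",
    "IndividualRecord",
    "SimulatedStudy",
    "simulate_panel",
    "simulate_individual",
    "simulate_family_table",
    "simulate_crosses",
    "simulate_run_years",
    "simulate_adult_table",
    "simulate_study",
]


@dataclass(frozen=True)
class PanelSpec:
    """Layout and divergence of a synthetic SNP reference panel.

    Defaults reproduce the study panel: 48 farm/wild-diagnostic plus 33
    further nuclear SNPs (81 nuclear in total) and 15 mitochondrial SNPs.
    ``fst_like_divergence`` in (0, 1] scales the wild/farmed allele-frequency
    separation at diagnostic loci; at 0 the two references coincide at every
    locus.
    """

    n_diagnostic: int = 48
    n_neutral: int = 33
    n_mt: int = 15
    fst_like_divergence: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("n_diagnostic", "n_neutral", "n_mt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fst_like_divergence < 1.0:
            raise ValueError(
                f"fst_like_divergence must lie in [0, 1), got {self.fst_like_divergence}"
            )

    @property
    def n_nuclear(self) -> int:
        return self.n_diagnostic + self.n_neutral


@dataclass(frozen=True)
class EffectConfig:
    """Generating effect sizes, distributions and noise levels.

    Coefficients are on the natural-log scale of the count/phenotype models;
    multiplicative egg-size effects are expressed as factors at full
    introgression or for hatchery background.  ``introgression_means`` are
    the (wild-born, hatchery-reared) group means on the proportion scale —
    used for broodstock and, via the logit transform, for run-year adults.
    """

    # log recapture-count model (best-model parameterisation)
    beta_intercept: float = -4.5564
    beta_dam_hatchery: float = 0.5560
    beta_introgression_wild_dam: float = 1.5145
    beta_introgression_hatchery_dam: float = -0.5018
    beta_log_eggs: float = 0.7069
    sigma_resid: float = 0.5
    sigma_year: float = 0.25
    # egg production
    egg_size_factor_hatchery_dam: float = 0.86
    egg_size_factor_introgression_wild_dam: float = 0.67
    egg_size_factor_introgression_hatchery_dam: float = 1.0
    base_egg_size_ml: float = 0.128
    sigma_egg_size: float = 0.10
    sigma_egg_size_year: float = 0.05
    egg_number_factor_hatchery_dam: float = 0.9
    fecundity_eggs_per_gram: float = 1.45
    sigma_egg_number: float = 0.15
    # dam size (g); meanlog calibrated so expected mean family size is ~10.3
    dam_weight_log_mean: float = math.log(6120.0)
    dam_weight_log_sd: float = 0.35
    # smolt growth
    smolt_pct_effect: float = 6.2
    smolt_pct_effect_wild: float = 5.0
    smolt_mean_hatchery_mm: float = 232.0
    smolt_mean_wild_mm: float = 152.0
    sigma_smolt: float = 0.08
    sigma_smolt_year: float = 0.04
    # sea-age multinomial model (log-odds of 1SW and 2SW vs 3+)
    seaage_a: tuple = (0.3, 0.8)
    seaage_b: tuple = (0.0, 0.0)
    seaage_d: tuple = (0.0, 0.0)
    seaage_sd: tuple = (0.3, 0.3)
    # broodstock composition and introgression distributions
    p_dam_hatchery: float = 0.55
    p_sire_hatchery: float = 0.65
    introgression_means: tuple = (0.113, 0.303)
    introgression_concentration: float = 10.0
    # run-year adult samples
    run_year_means: tuple = (0.092, 0.27)
    run_year_logit_sd_year: float = 0.3
    run_year_logit_sd_ind: float = 0.8
    # genotyping
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.04

    def __post_init__(self):
        for name in ("genotyping_error_rate", "missing_rate", "p_dam_hatchery", "p_sire_hatchery"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "sigma_resid", "sigma_year", "sigma_egg_size", "sigma_egg_size_year",
            "sigma_egg_number", "sigma_smolt", "sigma_smolt_year",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.seaage_sd):
            raise ValueError("seaage_sd entries must be >= 0")
        for name in ("introgression_means", "run_year_means"):
            for m in getattr(self, name):
                if not 0.0 < m < 1.0:
                    raise ValueError(f"{name} entries must lie in (0, 1), got {m}")
        if self.introgression_concentration <= 0:
            raise ValueError("introgression_concentration must be > 0")


@dataclass
class IndividualRecord:
    """One fish: genotypes, mtDNA haplotype, origin and ground truth."""

    individual_id: str
    genotypes: np.ndarray
    mt_haplotype: np.ndarray
    true_d: float
    origin: str = "wild"
    year: Optional[int] = None
    phenotypes: dict = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """A complete synthetic study with its generating configuration."""

    panel: ReferencePanel
    broodstock: pd.DataFrame
    broodstock_genotypes: pd.DataFrame
    broodstock_mt: pd.DataFrame
    crosses: pd.DataFrame
    offspring: pd.DataFrame
    offspring_genotypes: pd.DataFrame
    offspring_mt: pd.DataFrame
    truth: EffectConfig
    run_years: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# panel


def _split_freqs(rng, n: int, divergence: float):
    """Midpoint/offset construction: |wild - farmed| scales with divergence
    and vanishes exactly at divergence 0."""
    mid = rng.uniform(0.25, 0.75, size=n)
    width = 2.0 * np.minimum(mid, 1.0 - mid) * rng.uniform(0.85, 1.0, size=n)
    delta = divergence * width
    return mid - delta / 2.0, mid + delta / 2.0


def simulate_panel(
    spec: PanelSpec,
    calibrate: bool = True,
    n_calibration: int = 400,
) -> ReferencePanel:
    """Draw a reference panel according to ``spec`` (deterministic per seed).

    Diagnostic loci get wild/farmed frequency separations scaled by
    ``fst_like_divergence`` (farmed frequency of the counted, farm-associated
    allele is the larger); the remaining nuclear loci get near-equal
    frequencies whose small jitter also vanishes at divergence 0.

    When ``calibrate`` is true and the panel is informative, the scaling
    constants ``P_W``/``P_D`` are set to the Monte-Carlo average membership
    estimate over ``n_calibration`` pure wild and pure farmed individuals —
    the same construction the field uses to obtain those reference averages.
    Uninformative panels keep the default constants.
    """
    rng = substream(spec.seed, "panel")
    div = spec.fst_like_divergence

    w_diag, f_diag = _split_freqs(rng, spec.n_diagnostic, div)
    mid_neut = rng.uniform(0.25, 0.75, size=spec.n_neutral)
    jitter = 0.05 * div * rng.uniform(-1.0, 1.0, size=spec.n_neutral)
    w_neut = np.clip(mid_neut - jitter / 2.0, 0.01, 0.99)
    f_neut = np.clip(mid_neut + jitter / 2.0, 0.01, 0.99)
    w_mt, f_mt = _split_freqs(rng, spec.n_mt, div)

    locus_ids = tuple(
        [f"diag{i + 1:03d}" for i in range(spec.n_diagnostic)]
        + [f"neut{i + 1:03d}" for i in range(spec.n_neutral)]
    )
    mt_ids = tuple(f"mt{i + 1:02d}" for i in range(spec.n_mt))
    diagnostic = np.r_[
        np.ones(spec.n_diagnostic, dtype=bool), np.zeros(spec.n_neutral, dtype=bool)
    ]
    panel = ReferencePanel(
        locus_ids=locus_ids,
        wild_freq=np.concatenate([w_diag, w_neut]),
        farmed_freq=np.concatenate([f_diag, f_neut]),
        diagnostic=diagnostic,
        mt_locus_ids=mt_ids,
        mt_wild_freq=w_mt,
        mt_farmed_freq=f_mt,
    )

    if calibrate and spec.n_diagnostic > 0 and div > 0:
        cal_rng = substream(spec.seed, "panel-calibration")
        q_pure = np.r_[np.zeros(n_calibration), np.ones(n_calibration)]
        geno = _genotypes_from_mixture(panel, q_pure, cal_rng)
        q_hat = np.array([estimate_p_ind(g, panel).p_ind for g in geno])
        p_w = float(q_hat[:n_calibration].mean())
        p_d = float(q_hat[n_calibration:].mean())
        if p_d - p_w > 0.05:  # keep printed defaults for weakly informative panels
            panel = replace(panel, p_w=p_w, p_d=p_d)
    return panel


# ---------------------------------------------------------------------------
# individuals


def _genotypes_from_mixture(panel: ReferencePanel, qs: np.ndarray, rng) -> np.ndarray:
    """(n, L) genotype dosages: two allele draws from q*farmed + (1-q)*wild."""
    qs = np.asarray(qs, dtype=float)[:, None]
    p = qs * panel.farmed_freq[None, :] + (1.0 - qs) * panel.wild_freq[None, :]
    return rng.binomial(2, p).astype(float)


def _mt_from_mixture(panel: ReferencePanel, qs: np.ndarray, rng) -> np.ndarray:
    """(n, Lmt) haploid haplotypes; source population chosen w.p. q (farmed)."""
    n = len(qs)
    farmed_source = rng.random(n) < np.asarray(qs, dtype=float)
    freq = np.where(
        farmed_source[:, None], panel.mt_farmed_freq[None, :], panel.mt_wild_freq[None, :]
    )
    return (rng.random((n, panel.n_mt)) < freq).astype(float)


def simulate_individual(
    panel: ReferencePanel,
    true_D: float,
    seed: int | np.random.Generator = 0,
    individual_id: str = "ind",
    origin: str = "wild",
    year: Optional[int] = None,
) -> IndividualRecord:
    """Draw one admixed individual with mixture weight ``true_D``."""
    if not 0.0 <= true_D <= 1.0:
        raise ValueError(f"true_D must lie in [0, 1], got {true_D}")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "individual")
    geno = _genotypes_from_mixture(panel, np.array([true_D]), rng)[0]
    mt = _mt_from_mixture(panel, np.array([true_D]), rng)[0]
    return IndividualRecord(individual_id, geno, mt, float(true_D), origin, year)


def _inject_errors(
    geno: np.ndarray, rng, error_rate: float, missing_rate: float, ploidy: int = 2
) -> np.ndarray:
    """Symmetric single-allele flips plus missing dropouts, in place-safe copy."""
    g = geno.copy()
    if error_rate > 0:
        flip = rng.random(g.shape) < error_rate
        if ploidy == 2:
            direction = np.where(
                g == 0, 1.0, np.where(g == 2, -1.0, np.where(rng.random(g.shape) < 0.5, -1.0, 1.0))
            )
            g = np.where(flip, g + direction, g)
        else:
            g = np.where(flip, 1.0 - g, g)
    if missing_rate > 0:
        g = np.where(rng.random(g.shape) < missing_rate, np.nan, g)
    return g


# ---------------------------------------------------------------------------
# broodstock, crosses, offspring


def _beta_params(mean: float, conc: float):
    return mean * conc, (1.0 - mean) * conc


def _draw_introgression(rng, hatchery: np.ndarray, config: EffectConfig) -> np.ndarray:
    m_w, m_h = config.introgression_means
    c = config.introgression_concentration
    d = np.empty(len(hatchery))
    for h, m in ((0, m_w), (1, m_h)):
        idx = hatchery == h
        a, b = _beta_params(m, c)
        d[idx] = rng.beta(a, b, size=idx.sum())
    return d


def expected_midparent_introgression(config: EffectConfig) -> float:
    """Expected pair-average introgression under the configured mixture."""
    m_w, m_h = config.introgression_means
    e_dam = config.p_dam_hatchery * m_h + (1 - config.p_dam_hatchery) * m_w
    e_sire = config.p_sire_hatchery * m_h + (1 - config.p_sire_hatchery) * m_w
    return 0.5 * (e_dam + e_sire)


def simulate_family_table(
    config: EffectConfig,
    n_pairs: int = 85,
    years: int = 7,
    seed: int | np.random.Generator = 0,
    first_year: int = 2005,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Broodstock roster and family table (no genotypes; fast path).

    Returns ``(broodstock, crosses)``.  ``crosses`` carries one row per
    dam-sire pair with egg metrics, the realised (zero-truncated) number of
    offspring recaptured as adults, and all generating values.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "crosses")

    brood_year = first_year + (np.arange(n_pairs) % years)
    dam_h = (rng.random(n_pairs) < config.p_dam_hatchery).astype(int)
    sire_h = (rng.random(n_pairs) < config.p_sire_hatchery).astype(int)
    dam_d = _draw_introgression(rng, dam_h, config)
    sire_d = _draw_introgression(rng, sire_h, config)
    pair_d = 0.5 * (dam_d + sire_d)
    weight = np.exp(rng.normal(config.dam_weight_log_mean, config.dam_weight_log_sd, n_pairs))

    year_levels = np.arange(first_year, first_year + years)
    u_egg = dict(zip(year_levels, rng.normal(0.0, config.sigma_egg_size_year, years)))
    u_cnt = dict(zip(year_levels, rng.normal(0.0, config.sigma_year, years)))

    log_size = (
        np.log(config.base_egg_size_ml)
        + np.log(config.egg_size_factor_hatchery_dam) * dam_h
        + np.log(config.egg_size_factor_introgression_wild_dam) * dam_d * (1 - dam_h)
        + np.log(config.egg_size_factor_introgression_hatchery_dam) * dam_d * dam_h
        + np.array([u_egg[y] for y in brood_year])
        + rng.normal(0.0, config.sigma_egg_size, n_pairs)
    )
    egg_size = np.exp(log_size)
    diameter_mm = np.cbrt(6000.0 * egg_size / np.pi)
    eggs_per_25cm = np.maximum(1, np.rint(250.0 / diameter_mm)).astype(int)

    log_n_eggs = (
        np.log(config.fecundity_eggs_per_gram)
        + np.log(weight)
        + np.log(config.egg_number_factor_hatchery_dam) * dam_h
        + rng.normal(0.0, config.sigma_egg_number, n_pairs)
    )
    egg_number = np.maximum(1, np.rint(np.exp(log_n_eggs))).astype(int)
    total_volume = egg_number * egg_size

    eta_fixed = (
        config.beta_intercept
        + config.beta_dam_hatchery * dam_h
        + config.beta_introgression_wild_dam * pair_d * (1 - dam_h)
        + config.beta_introgression_hatchery_dam * pair_d * dam_h
        + config.beta_log_eggs * np.log(egg_number)
        + np.array([u_cnt[y] for y in brood_year])
    )
    # Zero-truncation: families are observed only through recaptured adults,
    # so realised counts are resampled until positive.
    counts = np.zeros(n_pairs, dtype=int)
    todo = np.ones(n_pairs, dtype=bool)
    for _ in range(1000):
        eps = rng.normal(0.0, config.sigma_resid, int(todo.sum()))
        counts[todo] = np.rint(np.exp(eta_fixed[todo] + eps)).astype(int)
        todo = counts < 1
        if not todo.any():
            break
    counts = np.maximum(counts, 1)

    dam_ids = [f"D{first_year}{i:04d}" for i in range(n_pairs)]
    sire_ids = [f"S{first_year}{i:04d}" for i in range(n_pairs)]
    broodstock = pd.DataFrame(
        {
            "individual_id": dam_ids + sire_ids,
            "sex": ["F"] * n_pairs + ["M"] * n_pairs,
            "brood_year": np.r_[brood_year, brood_year],
            "hatchery": np.r_[dam_h, sire_h],
            "origin": np.where(np.r_[dam_h, sire_h] == 1, "hatchery", "wild"),
            "true_d": np.r_[dam_d, sire_d],
            "weight_g": np.r_[weight, np.full(n_pairs, np.nan)],
        }
    )
    crosses = pd.DataFrame(
        {
            "dam_id": dam_ids,
            "sire_id": sire_ids,
            "brood_year": brood_year,
            "dam_hatchery": dam_h,
            "sire_hatchery": sire_h,
            "dam_true_d": dam_d,
            "sire_true_d": sire_d,
            "pair_introgression_true": pair_d,
            "dam_weight_g": weight,
            "egg_size_ml": egg_size,
            "eggs_per_25cm": eggs_per_25cm,
            "egg_number": egg_number,
            "total_egg_volume_ml": total_volume,
            "n_offspring": counts,
        }
    )
    return broodstock, crosses


_SEA_GROWTH_MM = {1: 380.0, 2: 560.0, 3: 680.0}


def _draw_sea_age(rng, d: np.ndarray, brood_year: np.ndarray, config: EffectConfig) -> np.ndarray:
    """Sea-age categories {1, 2, 3(=3+)} from the multinomial-logit model's
    own linear predictors, with per-year random effects on both contrasts."""
    years = np.unique(brood_year)
    t1 = dict(zip(years, rng.normal(0.0, config.seaage_sd[0], len(years))))
    t2 = dict(zip(years, rng.normal(0.0, config.seaage_sd[1], len(years))))
    year_mean = pd.Series(d).groupby(pd.Series(brood_year)).transform("mean").to_numpy()
    grand = float(pd.Series(d).groupby(pd.Series(brood_year)).mean().mean())
    a, b, dd = config.seaage_a, config.seaage_b, config.seaage_d
    x1 = a[0] + b[0] * d + dd[0] * (year_mean - grand) + np.array([t1[y] for y in brood_year])
    x2 = a[1] + b[1] * d + dd[1] * (year_mean - grand) + np.array([t2[y] for y in brood_year])
    denom = 1.0 + np.exp(x1) + np.exp(x2)
    p = np.c_[np.exp(x1) / denom, np.exp(x2) / denom, 1.0 / denom]
    u = rng.random(len(d))
    cum = np.cumsum(p, axis=1)
    return 1 + (u[:, None] > cum).sum(axis=1)


def _smolt_lengths(
    rng, d: np.ndarray, brood_year: np.ndarray, origin_hatchery: bool, config: EffectConfig,
    center_d: float,
) -> np.ndarray:
    slope = np.log1p(
        (config.smolt_pct_effect if origin_hatchery else config.smolt_pct_effect_wild) / 100.0
    )
    base = config.smolt_mean_hatchery_mm if origin_hatchery else config.smolt_mean_wild_mm
    years = np.unique(brood_year)
    u = dict(zip(years, rng.normal(0.0, config.sigma_smolt_year, len(years))))
    log_l = (
        np.log(base)
        + slope * (d - center_d)
        + np.array([u[y] for y in brood_year])
        + rng.normal(0.0, config.sigma_smolt, len(d))
    )
    return np.exp(log_l)


def _scale_readings(rng, smolt_mm: np.ndarray, sea_age: np.ndarray):
    """Adult capture length, total/smolt scale radii and annulus series.

    Scale radius is proportional to body length per fish (Lea-Dahl's
    premise), so back-calculation recovers the generated smolt length.
    """
    n = len(smolt_mm)
    growth = np.array([_SEA_GROWTH_MM[min(int(a), 3)] for a in sea_age])
    capture = smolt_mm + np.maximum(growth + rng.normal(0.0, 40.0, n), 50.0)
    k = np.maximum(rng.normal(0.05, 0.004, n), 0.02)
    total_r = k * capture
    smolt_r = k * smolt_mm
    annuli = []
    for i in range(n):
        fresh = [0.55 * smolt_r[i], smolt_r[i]]
        ages = int(min(sea_age[i], 3))
        sea = [
            smolt_r[i] + (total_r[i] - smolt_r[i]) * (j / (ages + 0.3))
            for j in range(1, ages + 1)
        ]
        annuli.append(fresh + sea)
    return capture, total_r, smolt_r, annuli


def simulate_crosses(
    config: EffectConfig,
    n_pairs: int = 85,
    years: int = 7,
    seed: int = 0,
    panel: Optional[ReferencePanel] = None,
    panel_spec: Optional[PanelSpec] = None,
    first_year: int = 2005,
) -> SimulatedStudy:
    """Full synthetic broodstock study: pedigree, genotypes and phenotypes.

    Offspring genotypes segregate Mendelian from parental genotypes before
    genotyping-error flips and dropouts; mtDNA haplotypes are inherited from
    the dam.  Broodstock are genotyped completely (the study re-genotyped
    broodstock to a 100% call rate); offspring calls are subject to both
    error and missingness.
    """
    if panel is None:
        panel = simulate_panel(panel_spec or PanelSpec(seed=seed))
    rng = substream(seed, "crosses")
    broodstock, crosses = simulate_family_table(config, n_pairs, years, rng, first_year)

    grng = substream(seed, "genotypes")
    parent_geno = _genotypes_from_mixture(panel, broodstock["true_d"].to_numpy(), grng)
    parent_mt = _mt_from_mixture(panel, broodstock["true_d"].to_numpy(), grng)
    parent_geno = _inject_errors(parent_geno, grng, config.genotyping_error_rate, 0.0)
    broodstock_genotypes = pd.DataFrame(
        parent_geno, index=broodstock["individual_id"], columns=list(panel.locus_ids)
    )
    broodstock_mt = pd.DataFrame(
        parent_mt, index=broodstock["individual_id"], columns=list(panel.mt_locus_ids)
    )

    # Mendelian segregation, vectorised over each family
    orng = substream(seed, "offspring")
    off_rows, off_geno, off_mt = [], [], []
    for row in crosses.itertuples():
        n_off = int(row.n_offspring)
        dam_g = broodstock_genotypes.loc[row.dam_id].to_numpy()
        sire_g = broodstock_genotypes.loc[row.sire_id].to_numpy()
        kid = np.zeros((n_off, panel.n_nuclear))
        for parent_g in (dam_g, sire_g):
            transmit = np.where(
                parent_g[None, :] == 1,
                (orng.random((n_off, panel.n_nuclear)) < 0.5).astype(float),
                (parent_g[None, :] / 2.0),
            )
            kid += transmit
        mt = np.tile(broodstock_mt.loc[row.dam_id].to_numpy(), (n_off, 1))
        kid = _inject_errors(kid, orng, config.genotyping_error_rate, config.missing_rate)
        mt = _inject_errors(mt, orng, config.genotyping_error_rate, config.missing_rate, ploidy=1)
        mid_d = 0.5 * (row.dam_true_d + row.sire_true_d)
        for i in range(n_off):
            off_rows.append(
                {
                    "individual_id": f"O{row.dam_id[1:]}_{i:03d}",
                    "dam_id": row.dam_id,
                    "sire_id": row.sire_id,
                    "brood_year": row.brood_year,
                    "true_d": mid_d,
                }
            )
        off_geno.append(kid)
        off_mt.append(mt)

    offspring = pd.DataFrame(off_rows)
    geno_mat = np.vstack(off_geno)
    mt_mat = np.vstack(off_mt)

    prng = substream(seed, "offspring-phenotypes")
    d = offspring["true_d"].to_numpy()
    by = offspring["brood_year"].to_numpy()
    sea_age = _draw_sea_age(prng, d, by, config)
    smolt = _smolt_lengths(prng, d, by, True, config, expected_midparent_introgression(config))
    capture, total_r, smolt_r, annuli = _scale_readings(prng, smolt, sea_age)
    offspring["origin"] = "hatchery"
    offspring["sea_age"] = sea_age
    offspring["smolt_length_true_mm"] = smolt
    offspring["capture_length_mm"] = capture
    offspring["total_radius"] = total_r
    offspring["smolt_radius"] = smolt_r
    offspring["smolt_annulus"] = 1  # 0-based index of the second freshwater annulus
    offspring["annulus_radii"] = [";".join(f"{r:.6g}" for r in a) for a in annuli]
    offspring["run_year"] = offspring["brood_year"] + 2 + offspring["sea_age"]

    ids = offspring["individual_id"]
    return SimulatedStudy(
        panel=panel,
        broodstock=broodstock,
        broodstock_genotypes=broodstock_genotypes,
        broodstock_mt=broodstock_mt,
        crosses=crosses,
        offspring=offspring,
        offspring_genotypes=pd.DataFrame(geno_mat, index=ids, columns=list(panel.locus_ids)),
        offspring_mt=pd.DataFrame(mt_mat, index=ids, columns=list(panel.mt_locus_ids)),
        truth=config,
    )


def _logit(p):
    return np.log(p / (1.0 - p))


def simulate_run_years(
    config: EffectConfig,
    n_years: int = 20,
    n_per_group_per_year: int = 70,
    seed: int | np.random.Generator = 0,
    first_year: int = 1985,
) -> pd.DataFrame:
    """Run-year samples of returning adults with per-individual ``p_ind``.

    Group means are set on the logit scale to ``config.run_year_means``
    (wild-born, hatchery-reared); each group-year mean receives independent
    year noise and individuals receive logit-scale noise on top.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "run-years")
    m_w, m_h = config.run_year_means
    rows = []
    for i in range(n_years):
        year = first_year + i
        for origin, m, h in (("wild", m_w, 0), ("hatchery", m_h, 1)):
            mu = _logit(m) + rng.normal(0.0, config.run_year_logit_sd_year)
            logits = mu + rng.normal(0.0, config.run_year_logit_sd_ind, n_per_group_per_year)
            p = 1.0 / (1.0 + np.exp(-logits))
            for j, pj in enumerate(p):
                rows.append(
                    {
                        "individual_id": f"R{year}{origin[0].upper()}{j:03d}",
                        "run_year": year,
                        "origin": origin,
                        "hatchery": h,
                        "p_ind": pj,
                    }
                )
    return pd.DataFrame(rows)


def simulate_adult_table(
    config: EffectConfig,
    n_adults: int = 500,
    years: int = 7,
    origin: str = "hatchery",
    seed: int | np.random.Generator = 0,
    first_year: int = 2005,
) -> pd.DataFrame:
    """Adult spawners with true introgression, sea age and smolt length.

    A direct generator for the growth and sea-age analyses: introgression is
    drawn from the configured Beta for the origin group and smolt length
    from the log-linear growth model.
    """
    if origin not in ("hatchery", "wild"):
        raise ValueError("origin must be 'hatchery' or 'wild'")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "adults")
    hatch = origin == "hatchery"
    m = config.run_year_means[1] if hatch else config.run_year_means[0]
    a, b = _beta_params(m, config.introgression_concentration)
    d = rng.beta(a, b, n_adults)
    brood_year = first_year + (np.arange(n_adults) % years)
    sea_age = _draw_sea_age(rng, d, brood_year, config)
    smolt = _smolt_lengths(rng, d, brood_year, hatch, config, m)
    capture, total_r, smolt_r, annuli = _scale_readings(rng, smolt, sea_age)
    return pd.DataFrame(
        {
            "individual_id": [f"A{i:05d}" for i in range(n_adults)],
            "origin": origin,
            "brood_year": brood_year,
            "introgression": d,
            "sea_age": sea_age,
            "smolt_length_true_mm": smolt,
            "capture_length_mm": capture,
            "total_radius": total_r,
            "smolt_radius": smolt_r,
            "smolt_annulus": 1,
            "annulus_radii": [";".join(f"{r:.6g}" for r in a_) for a_ in annuli],
        }
    )


def simulate_study(
    config: EffectConfig = EffectConfig(),
    panel_spec: Optional[PanelSpec] = None,
    n_pairs: int = 85,
    years: int = 7,
    n_run_years: int = 20,
    n_per_group_per_year: int = 70,
    seed: int = 0,
) -> SimulatedStudy:
    """Complete study: broodstock crosses plus run-year adult samples."""
    study = simulate_crosses(
        config, n_pairs=n_pairs, years=years, seed=seed,
        panel_spec=panel_spec or PanelSpec(seed=seed),
    )
    study.run_years = simulate_run_years(
        config, n_years=n_run_years, n_per_group_per_year=n_per_group_per_year,
        seed=substream(seed, "run-years"),
    )
    return study
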