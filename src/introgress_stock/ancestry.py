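"""Individual farmed-ancestry estimation from diagnostic SNPs.

Each fish carries genotypes (0/1/2 dosage of the farm-associated allele) at
a panel of biallelic nuclear SNPs.  A subset of loci is *diagnostic*: their
allele frequencies differ strongly between wild and farmed reference
populations.  The probability of farmed membership ``P_ind`` for an
individual is the admixture proportion ``q`` maximising the binomial
log-likelihood of its diagnostic genotypes under per-locus mixture
frequencies ``q * farmed + (1 - q) * wild``.

``P_ind`` is then rescaled to a proportion of farmed ancestry

    D = (P_ind - P_W) / (P_D - P_W)

where ``P_W`` and ``P_D`` are the average membership estimates in pure wild
and pure farmed reference samples.  Because ``P_D`` is below one and ``P_W``
above zero, raw ``D`` may fall slightly outside [0, 1]; raw values are
reported (statistical models consume them) with an optional clamp for
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "ReferencePanel",
    "AncestryEstimate",
    "estimate_p_ind",
    "compute_D",
    "batch_estimate",
    "estimates_to_frame",
]

#: Reference scaling constants: average membership probability of pure wild
#: and pure farmed reference samples on the estimator's scale.
DEFAULT_P_W = 0.0644
DEFAULT_P_D = 0.903

# Reference frequencies are truncated away from 0/1 before entering the
# likelihood so fixed loci cannot produce infinite log-likelihoods.
_FREQ_FLOOR = 1e-4


@dataclass(frozen=True)
class ReferencePanel:
    """Per-locus wild/farmed allele frequencies and panel metadata.

    Nuclear loci carry a ``diagnostic`` flag; only diagnostic loci enter
    ancestry estimation.  Mitochondrial loci are haploid and used solely for
    maternity verification (and, in simulation, maternal inheritance).
    """

    locus_ids: tuple
    wild_freq: np.ndarray
    farmed_freq: np.ndarray
    diagnostic: np.ndarray
    mt_locus_ids: tuple = ()
    mt_wild_freq: np.ndarray = field(default_factory=lambda: np.empty(0))
    mt_farmed_freq: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_w: float = DEFAULT_P_W
    p_d: float = DEFAULT_P_D

    def __post_init__(self):
        wild = np.asarray(self.wild_freq, dtype=float)
        farmed = np.asarray(self.farmed_freq, dtype=float)
        diag = np.asarray(self.diagnostic, dtype=bool)
        object.__setattr__(self, "wild_freq", wild)
        object.__setattr__(self, "farmed_freq", farmed)
        object.__setattr__(self, "diagnostic", diag)
        object.__setattr__(self, "mt_wild_freq", np.asarray(self.mt_wild_freq, dtype=float))
        object.__setattr__(self, "mt_farmed_freq", np.asarray(self.mt_farmed_freq, dtype=float))
        n = len(self.locus_ids)
        if not (wild.shape == farmed.shape == diag.shape == (n,)):
            raise ValueError("locus_ids, wild_freq, farmed_freq and diagnostic must have equal length")
        used = diag
        for name, f in (("wild", wild[used]), ("farmed", farmed[used])):
            if np.any((f <= 0.0) | (f >= 1.0)):
                raise ValueError(f"{name} frequencies at diagnostic loci must lie strictly in (0, 1)")
        if not self.p_d > self.p_w:
            raise ValueError(f"P_D ({self.p_d}) must exceed P_W ({self.p_w})")

    @property
    def n_nuclear(self) -> int:
        return len(self.locus_ids)

    @property
    def n_diagnostic(self) -> int:
        return int(self.diagnostic.sum())

    @property
    def n_mt(self) -> int:
        return len(self.mt_locus_ids)


@dataclass(frozen=True)
class AncestryEstimate:
    """Point estimate of farmed membership and rescaled farmed ancestry."""

    individual_id: str
    p_ind: float
    D: float
    n_loci_used: int
    se_p_ind: float
    estimable: bool = True

    @staticmethod
    def unestimable(individual_id: str) -> "AncestryEstimate":
        return AncestryEstimate(individual_id, np.nan, np.nan, 0, np.nan, estimable=False)


def _diag_freqs(panel: ReferencePanel):
    w = np.clip(panel.wild_freq[panel.diagnostic], _FREQ_FLOOR, 1 - _FREQ_FLOOR)
    f = np.clip(panel.farmed_freq[panel.diagnostic], _FREQ_FLOOR, 1 - _FREQ_FLOOR)
    return w, f


def _loglik(q: float, g: np.ndarray, w: np.ndarray, f: np.ndarray) -> float:
    p = q * f + (1.0 - q) * w
    p = np.clip(p, _FREQ_FLOOR / 2, 1 - _FREQ_FLOOR / 2)
    return float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


def estimate_p_ind(
    genotypes: Sequence[float] | np.ndarray,
    panel: ReferencePanel,
    individual_id: str = "",
) -> AncestryEstimate:
    """Maximum-likelihood farmed-membership probability for one individual.

    ``genotypes`` is the 0/1/2 dosage vector over the panel's *nuclear* loci
    (NaN = missing call).  Only diagnostic, non-missing loci enter the
    likelihood.  With every diagnostic locus missing the estimate is flagged
    unestimable rather than silently returned as 0.
    """
    g_all = np.asarray(genotypes, dtype=float)
    if g_all.shape != (panel.n_nuclear,):
        raise ValueError(
            f"genotype vector has length {g_all.shape}, panel has {panel.n_nuclear} nuclear loci"
        )
    g = g_all[panel.diagnostic]
    mask = ~np.isnan(g)
    if not mask.any():
        return AncestryEstimate.unestimable(individual_id)
    w, f = _diag_freqs(panel)
    g, w, f = g[mask], w[mask], f[mask]
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype calls must be 0, 1, 2 or NaN")

    res = minimize_scalar(
        lambda q: -_loglik(q, g, w, f),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(np.clip(res.x, 0.0, 1.0))
    # The bounded search can stall a tolerance away from an endpoint that is
    # the true maximiser; compare against both boundaries explicitly.
    for q_b in (0.0, 1.0):
        if _loglik(q_b, g, w, f) > _loglik(q_hat, g, w, f):
            q_hat = q_b

    # Curvature-based standard error: the observed information is
    # sum((f-w)^2 * (g/p^2 + (2-g)/(1-p)^2)), strictly positive.
    p = np.clip(q_hat * f + (1.0 - q_hat) * w, _FREQ_FLOOR / 2, 1 - _FREQ_FLOOR / 2)
    info = float(np.sum((f - w) ** 2 * (g / p**2 + (2.0 - g) / (1.0 - p) ** 2)))
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan

    return AncestryEstimate(
        individual_id=individual_id,
        p_ind=q_hat,
        D=compute_D(q_hat, panel),
        n_loci_used=int(mask.sum()),
        se_p_ind=se,
    )


def compute_D(p_ind: float, panel: ReferencePanel) -> float:
    """Rescale a membership probability to proportion farmed ancestry.

    D = (P_ind - P_W) / (P_D - P_W), evaluated exactly and without clamping.
    """
    if panel.p_d == panel.p_w:
        raise ValueError("D is undefined when P_D equals P_W")
    return (p_ind - panel.p_w) / (panel.p_d - panel.p_w)


def batch_estimate(
    genotypes: pd.DataFrame,
    panel: ReferencePanel,
    clamp: bool = False,
) -> list[AncestryEstimate]:
    """Estimate ancestry for every row of an individuals x loci matrix.

    Column ids must match the panel's nuclear loci (order included).  Rows
    that cannot be estimated (all diagnostic loci missing) are returned
    flagged, never dropped, so output order matches input order.
    """
    cols = list(genotypes.columns)
    expected = list(panel.locus_ids)
    if cols != expected:
        unknown = [c for c in cols if c not in set(expected)]
        missing = [c for c in expected if c not in set(cols)]
        raise ValueError(
            "genotype columns do not match panel loci; "
            f"unknown={unknown[:5]}, missing={missing[:5]} "
            "(columns must appear in panel order)"
        )
    out = []
    for idx, row in zip(genotypes.index, genotypes.to_numpy(dtype=float)):
        est = estimate_p_ind(row, panel, individual_id=str(idx))
        if clamp and est.estimable:
            est = AncestryEstimate(
                est.individual_id,
                est.p_ind,
                float(np.clip(est.D, 0.0, 1.0)),
                est.n_loci_used,
                est.se_p_ind,
            )
        out.append(est)
    return out


def estimates_to_frame(estimates: Sequence[AncestryEstimate]) -> pd.DataFrame:
    """Tabulate a collection of ancestry estimates."""
    return pd.DataFrame(
        {
            "individual_id": [e.individual_id for e in estimates],
            "p_ind": [e.p_ind for e in estimates],
            "D": [e.D for e in estimates],
            "n_loci_used": [e.n_loci_used for e in estimates],
            "se_p_ind": [e.se_p_ind for e in estimates],
            "estimable": [e.estimable for e in estimates],
        }
    )
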