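"""Parentage assignment by Mendelian exclusion with mismatch tolerance.

Recaptured adults are matched against all dam x sire combinations of the
broodstock used in their assigned brood year +/- 1 (aging from scales can be
off by a year).  A locus is a mismatch when no ordered pair of transmitted
alleles — one from each candidate parent — can produce the offspring
genotype; loci with any missing call among the trio are skipped.  The pair
with the fewest mismatches wins when unique and within tolerance (default
2 mismatches, the level the study accepted after re-genotyping); ties are
reported as ambiguous, never broken silently.  Maternity of an assignment
is verified separately against the dam's mitochondrial haplotype, which
never enters the exclusion itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrioMatch",
    "AssignmentResult",
    "count_mismatches",
    "verify_maternity",
    "assign_offspring",
    "assign_all",
    "build_family_table",
]


@dataclass(frozen=True)
class TrioMatch:
    offspring_id: str
    dam_id: str
    sire_id: str
    mismatch_count: int
    loci_compared: int
    mt_consistent: str = "untestable"  # consistent / inconsistent / untestable


@dataclass(frozen=True)
class AssignmentResult:
    offspring_id: str
    status: str  # assigned / unassigned / ambiguous / excluded_missingness
    best: Optional[TrioMatch]
    n_candidate_pairs: int
    brood_year: Optional[int]


def _transmit_range(g: np.ndarray):
    """Min and max allele dosage a parent with genotype g can transmit."""
    return (g == 2).astype(float), (g > 0).astype(float)


def count_mismatches(
    offspring: Sequence[float], dam: Sequence[float], sire: Sequence[float]
) -> tuple[int, int]:
    """Mendelian mismatch count and number of jointly non-missing loci.

    A mismatch is a locus where the offspring dosage falls outside the
    attainable range of transmitted-allele sums; because each parent
    contributes 0 or 1 copies, the attainable set is a contiguous range.
    """
    o = np.asarray(offspring, dtype=float)
    d = np.asarray(dam, dtype=float)
    s = np.asarray(sire, dtype=float)
    if not (o.shape == d.shape == s.shape):
        raise ValueError("offspring, dam and sire genotype vectors must have equal length")
    ok = ~(np.isnan(o) | np.isnan(d) | np.isnan(s))
    dmin, dmax = _transmit_range(d[ok])
    smin, smax = _transmit_range(s[ok])
    oo = o[ok]
    mism = (oo < dmin + smin) | (oo > dmax + smax)
    return int(mism.sum()), int(ok.sum())


def verify_maternity(
    offspring_mt: Sequence[float], dam_mt: Sequence[float]
) -> str:
    """Compare haploid mtDNA haplotypes: consistent iff identical at every
    jointly non-missing locus; untestable when none are jointly called."""
    o = np.asarray(offspring_mt, dtype=float)
    d = np.asarray(dam_mt, dtype=float)
    if o.shape != d.shape:
        raise ValueError("mt haplotypes must cover the same locus set")
    ok = ~(np.isnan(o) | np.isnan(d))
    if not ok.any():
        return "untestable"
    return "consistent" if np.array_equal(o[ok], d[ok]) else "inconsistent"


def assign_offspring(
    offspring_id: str,
    offspring_genotypes: Sequence[float],
    offspring_brood_year: int,
    roster: pd.DataFrame,
    roster_genotypes: pd.DataFrame,
    offspring_mt: Optional[Sequence[float]] = None,
    roster_mt: Optional[pd.DataFrame] = None,
    max_mismatch: int = 2,
    missing_threshold: float = 0.20,
    year_window: int = 1,
) -> AssignmentResult:
    """Score one offspring against every candidate dam x sire pair.

    ``roster`` needs columns individual_id, sex ('F'/'M') and brood_year;
    ``roster_genotypes`` is indexed by individual_id over the same nuclear
    loci as the offspring vector.  Offspring with a missing-call fraction
    above ``missing_threshold`` are excluded before any scoring.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    o = np.asarray(offspring_genotypes, dtype=float)
    n_loci = o.shape[0]
    if np.isnan(o).sum() / n_loci > missing_threshold:
        return AssignmentResult(offspring_id, "excluded_missingness", None, 0, offspring_brood_year)

    candidate_years = range(offspring_brood_year - year_window, offspring_brood_year + year_window + 1)
    o_ok = ~np.isnan(o)

    best: list[tuple[str, str, int, int, int]] = []  # dam, sire, mism, compared, year
    best_mism = None
    n_pairs = 0
    for year in candidate_years:
        in_year = roster[roster["brood_year"] == year]
        dams = in_year[in_year["sex"] == "F"]["individual_id"].tolist()
        sires = in_year[in_year["sex"] == "M"]["individual_id"].tolist()
        if not dams or not sires:
            continue
        dam_g = roster_genotypes.loc[dams].to_numpy(dtype=float)
        sire_g = roster_genotypes.loc[sires].to_numpy(dtype=float)
        dmin, dmax = _transmit_range(dam_g)
        smin, smax = _transmit_range(sire_g)
        dmiss = np.isnan(dam_g)
        smiss = np.isnan(sire_g)
        for di, dam in enumerate(dams):
            ok = o_ok & ~dmiss[di][None, :] & ~smiss  # (n_sires, L)
            lo = dmin[di][None, :] + smin
            hi = dmax[di][None, :] + smax
            mism_mat = ((o[None, :] < lo) | (o[None, :] > hi)) & ok
            mism_counts = mism_mat.sum(axis=1)
            compared = ok.sum(axis=1)
            n_pairs += len(sires)
            for si, sire in enumerate(sires):
                m = int(mism_counts[si])
                if best_mism is None or m < best_mism:
                    best_mism = m
                    best = [(dam, sire, m, int(compared[si]), year)]
                elif m == best_mism:
                    best.append((dam, sire, m, int(compared[si]), year))

    if n_pairs == 0:
        raise ValueError(f"no candidate broodstock pairs for brood year {offspring_brood_year}")
    if best_mism is None or best_mism > max_mismatch:
        return AssignmentResult(offspring_id, "unassigned", None, n_pairs, offspring_brood_year)
    if len(best) > 1:
        return AssignmentResult(offspring_id, "ambiguous", None, n_pairs, offspring_brood_year)

    dam, sire, mism, compared, year = best[0]
    mt_state = "untestable"
    if offspring_mt is not None and roster_mt is not None and dam in roster_mt.index:
        mt_state = verify_maternity(offspring_mt, roster_mt.loc[dam].to_numpy(dtype=float))
    match = TrioMatch(offspring_id, dam, sire, mism, compared, mt_state)
    return AssignmentResult(offspring_id, "assigned", match, n_pairs, year)


def assign_all(
    offspring: pd.DataFrame,
    offspring_genotypes: pd.DataFrame,
    roster: pd.DataFrame,
    roster_genotypes: pd.DataFrame,
    offspring_mt: Optional[pd.DataFrame] = None,
    roster_mt: Optional[pd.DataFrame] = None,
    max_mismatch: int = 2,
    missing_threshold: float = 0.20,
    year_window: int = 1,
) -> pd.DataFrame:
    """Assign every offspring row; returns one table row per offspring."""
    rows = []
    for rec in offspring.itertuples():
        oid = rec.individual_id
        res = assign_offspring(
            oid,
            offspring_genotypes.loc[oid].to_numpy(dtype=float),
            int(rec.brood_year),
            roster,
            roster_genotypes,
            offspring_mt=None if offspring_mt is None else offspring_mt.loc[oid].to_numpy(dtype=float),
            roster_mt=roster_mt,
            max_mismatch=max_mismatch,
            missing_threshold=missing_threshold,
            year_window=year_window,
        )
        rows.append(
            {
                "individual_id": oid,
                "status": res.status,
                "dam_id": res.best.dam_id if res.best else None,
                "sire_id": res.best.sire_id if res.best else None,
                "mismatch_count": res.best.mismatch_count if res.best else None,
                "loci_compared": res.best.loci_compared if res.best else None,
                "mt_consistent": res.best.mt_consistent if res.best else None,
                "n_candidate_pairs": res.n_candidate_pairs,
                "brood_year": res.brood_year,
            }
        )
    return pd.DataFrame(rows)


def build_family_table(
    assignments: pd.DataFrame,
    broodstock_info: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Collapse assignments into one row per dam-sire pair with >= 1 offspring.

    When ``broodstock_info`` (individual_id, hatchery flag and an ancestry
    column ``D`` or ``true_d``) is given, the pair's introgression is the
    dam-sire average and the dam's background is attached — the covariates
    of the reproductive-success models.
    """
    assigned = assignments[assignments["status"] == "assigned"]
    if assigned.empty:
        cols = ["dam_id", "sire_id", "brood_year", "n_offspring"]
        return pd.DataFrame(columns=cols)
    fam = (
        assigned.groupby(["dam_id", "sire_id"], as_index=False)
        .agg(brood_year=("brood_year", "first"), n_offspring=("individual_id", "count"))
    )
    if broodstock_info is not None:
        info = broodstock_info.set_index("individual_id")
        d_col = "D" if "D" in info.columns else "true_d"
        fam["dam_introgression"] = fam["dam_id"].map(info[d_col])
        fam["sire_introgression"] = fam["sire_id"].map(info[d_col])
        fam["pair_introgression"] = 0.5 * (fam["dam_introgression"] + fam["sire_introgression"])
        if "hatchery" in info.columns:
            fam["dam_hatchery"] = fam["dam_id"].map(info["hatchery"]).astype(int)
            fam["sire_hatchery"] = fam["sire_id"].map(info["hatchery"]).astype(int)
    return fam
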