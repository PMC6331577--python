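"""End-to-end orchestration: simulate -> ancestry -> parentage -> phenotypes
-> inference, as one reproducible, fully-logged run.

A run is described by a :class:`RunConfig` (YAML on disk).  Every stage
persists its table under the output directory with a provenance header
(seed, config hash), so a run can be audited or partially re-executed.  In
synthetic mode the report appends recovery diagnostics comparing each
fitted coefficient with its generating value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .ancestry import batch_estimate, estimates_to_frame
from .inference import (
    fit_count_model_suite,
    fit_egg_models,
    fit_introgression_glmm,
    fit_smolt_length_model,
    wald_ci_transform,
)
from .io import config_hash, write_genotypes, write_panel, write_table
from .parentage import assign_all, build_family_table
from .phenotypes import add_back_calculated_smolt_length
from .simulate import EffectConfig, PanelSpec, simulate_study

__all__ = ["RunConfig", "StudyReport", "validate_config", "run_all"]

log = logging.getLogger("introgress_stock")


@dataclass
class RunConfig:
    """Fully-typed configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    n_pairs: int = 85
    years: int = 7
    n_run_years: int = 20
    n_per_group_per_year: int = 70
    panel: PanelSpec = field(default_factory=PanelSpec)
    effects: EffectConfig = field(default_factory=EffectConfig)
    max_mismatch: int = 2
    missing_threshold: float = 0.20
    year_window: int = 1
    alpha: float = 0.05
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyReport:
    """Per-stage summaries plus truth-vs-estimate diagnostics."""

    seed: int
    config_hash: str
    n_broodstock: int = 0
    n_offspring: int = 0
    ancestry: dict = field(default_factory=dict)
    assignment_counts: dict = field(default_factory=dict)
    n_families: int = 0
    model_fits: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)

    def validate_counts(self) -> None:
        total = sum(self.assignment_counts.values())
        if total != self.n_offspring:
            raise AssertionError(
                f"assignment statuses ({total}) do not reconcile with offspring ({self.n_offspring})"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)

    def to_text(self) -> str:
        lines = [
            f"introgress-stock {__version__} run report (seed={self.seed}, config={self.config_hash})",
            f"broodstock: {self.n_broodstock}; offspring: {self.n_offspring}",
            "assignment: " + ", ".join(f"{k}={v}" for k, v in self.assignment_counts.items()),
            f"families with >=1 recapture: {self.n_families}",
        ]
        for name, block in self.model_fits.items():
            lines.append(f"[{name}]")
            for term, vals in block.items():
                if isinstance(vals, dict) and "estimate" in vals and "se" in vals:
                    lines.append(f"  {term}: {vals['estimate']:+.4f} +/- {vals['se']:.4f}")
                elif isinstance(vals, dict) and "estimate" in vals:
                    lines.append(
                        f"  {term}: {vals['estimate']:+.4f} "
                        f"(95% CI {vals.get('ci_low', float('nan')):.4f} to "
                        f"{vals.get('ci_high', float('nan')):.4f})"
                    )
                else:
                    lines.append(f"  {term}: {vals}")
        if self.recovery:
            lines.append("[truth recovery]")
            for k, v in self.recovery.items():
                lines.append(f"  {k}: estimate {v['estimate']:+.4f} vs truth {v['truth']:+.4f}")
        return "\n".join(lines)


_KNOWN_TOP = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    All schema violations are collected and reported together; unknown keys
    (top-level or inside the panel/effects blocks) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")

    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown configuration key: {key!r}")

    panel_kwargs = raw.get("panel", {}) or {}
    effect_kwargs = raw.get("effects", {}) or {}
    for block, cls, kwargs in (
        ("panel", PanelSpec, panel_kwargs),
        ("effects", EffectConfig, effect_kwargs),
    ):
        known = {f.name for f in dataclasses.fields(cls)}
        for key in kwargs:
            if key not in known:
                errors.append(f"unknown key in {block!r} block: {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")

    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    kwargs = {k: v for k, v in raw.items() if k not in ("panel", "effects")}
    try:
        config = RunConfig(
            panel=PanelSpec(**panel_kwargs),
            effects=EffectConfig(**effect_kwargs),
            **kwargs,
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc

    outdir = Path(config.outdir)
    if not outdir.exists():
        outdir.mkdir(parents=True)
        log.info("created output directory %s", outdir)
    return config


def _fit_block(fit, transform: Optional[str] = None) -> dict:
    block = {}
    for name, est, se in zip(fit.coef_names, fit.coef, fit.se):
        entry = {"estimate": float(est), "se": float(se)}
        if transform and name != "Intercept":
            point, lo, hi = wald_ci_transform(est, se, transform)
            entry.update({"transformed": point, "ci_low": lo, "ci_high": hi})
        block[name] = entry
    block["aic"] = float(fit.aic)
    block["loglik"] = float(fit.loglik)
    block["re_var"] = None if fit.re_var is None else float(fit.re_var)
    return block


def run_all(config: RunConfig) -> StudyReport:
    """Execute all stages in order; halt with the stage name on failure."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    hdr = {"config": chash}
    report = StudyReport(seed=config.seed, config_hash=chash)
    stage = "simulate"
    try:
        t0 = time.time()
        study = simulate_study(
            config.effects,
            panel_spec=dataclasses.replace(config.panel, seed=config.seed),
            n_pairs=config.n_pairs,
            years=config.years,
            n_run_years=config.n_run_years,
            n_per_group_per_year=config.n_per_group_per_year,
            seed=config.seed,
        )
        write_panel(study.panel, outdir / "panel.tsv", seed=config.seed)
        write_table(study.broodstock, outdir / "broodstock.tsv", config.seed, hdr)
        write_table(study.crosses, outdir / "crosses_truth.tsv", config.seed, hdr)
        write_table(study.offspring, outdir / "offspring.tsv", config.seed, hdr)
        write_table(study.run_years, outdir / "run_years.tsv", config.seed, hdr)
        write_genotypes(study.broodstock_genotypes, outdir / "broodstock_genotypes.tsv", config.seed, hdr)
        write_genotypes(study.broodstock_mt, outdir / "broodstock_mt.tsv", config.seed, hdr)
        write_genotypes(study.offspring_genotypes, outdir / "offspring_genotypes.tsv", config.seed, hdr)
        write_genotypes(study.offspring_mt, outdir / "offspring_mt.tsv", config.seed, hdr)
        report.n_broodstock = len(study.broodstock)
        report.n_offspring = len(study.offspring)
        log.info("simulated %d broodstock, %d offspring in %.1fs",
                 report.n_broodstock, report.n_offspring, time.time() - t0)

        stage = "ancestry"
        brood_est = estimates_to_frame(batch_estimate(study.broodstock_genotypes, study.panel))
        off_est = estimates_to_frame(batch_estimate(study.offspring_genotypes, study.panel))
        ancestry_table = pd.concat([brood_est, off_est], ignore_index=True)
        write_table(ancestry_table, outdir / "ancestry.tsv", config.seed, hdr)
        report.ancestry = {
            "n_estimated": int(ancestry_table["estimable"].sum()),
            "n_unestimable": int((~ancestry_table["estimable"]).sum()),
            "mean_D_broodstock": float(brood_est["D"].mean()),
            "mean_D_offspring": float(off_est["D"].mean()),
        }

        stage = "parentage"
        assignments = assign_all(
            study.offspring,
            study.offspring_genotypes,
            study.broodstock,
            study.broodstock_genotypes,
            offspring_mt=study.offspring_mt,
            roster_mt=study.broodstock_mt,
            max_mismatch=config.max_mismatch,
            missing_threshold=config.missing_threshold,
            year_window=config.year_window,
        )
        write_table(assignments, outdir / "assignments.tsv", config.seed, hdr)
        counts = assignments["status"].value_counts().to_dict()
        for status in ("assigned", "unassigned", "ambiguous", "excluded_missingness"):
            counts.setdefault(status, 0)
        report.assignment_counts = {k: int(v) for k, v in counts.items()}
        report.validate_counts()

        brood_info = study.broodstock[["individual_id", "hatchery"]].merge(
            brood_est[["individual_id", "D"]], on="individual_id"
        )
        families = build_family_table(assignments, brood_info)
        families = families.merge(
            study.crosses[["dam_id", "sire_id", "egg_number", "egg_size_ml", "dam_weight_g"]],
            on=["dam_id", "sire_id"],
            how="left",
        )
        write_table(families, outdir / "families.tsv", config.seed, hdr)
        report.n_families = len(families)

        stage = "phenotypes"
        adults = add_back_calculated_smolt_length(study.offspring)
        adults = adults.merge(off_est[["individual_id", "D"]], on="individual_id")
        adults = adults.rename(columns={"D": "introgression"})
        write_table(adults, outdir / "phenotypes.tsv", config.seed, hdr)

        stage = "inference"
        best, ladder = fit_count_model_suite(families)
        report.model_fits["count_best"] = _fit_block(best, transform="exp")
        report.model_fits["count_ladder"] = {
            f.label: {"aic": float(f.aic), "delta_aic": float(f.delta_aic)} for f in ladder
        }
        size_fit, number_fit = fit_egg_models(families)
        report.model_fits["egg_size"] = _fit_block(size_fit, transform="exp")
        report.model_fits["egg_number"] = _fit_block(number_fit, transform="exp")
        smolt_fit, pct = fit_smolt_length_model(adults)
        report.model_fits["smolt_length"] = _fit_block(smolt_fit)
        report.model_fits["smolt_length"]["percent_effect"] = {
            "estimate": pct[0], "ci_low": pct[1], "ci_high": pct[2]
        }
        glmm = fit_introgression_glmm(study.run_years, alpha=config.alpha)
        write_table(glmm.to_frame(), outdir / "run_year_glmm.tsv", config.seed, hdr)
        report.model_fits["run_year_glmm"] = {
            "grand_mean_wild": glmm.grand_mean_wild,
            "grand_mean_hatchery": glmm.grand_mean_hatchery,
            "n_significant_years": int(glmm.significant.sum()),
            "n_testable_years": int(glmm.testable.sum()),
            "sigma2": glmm.sigma2,
        }

        truth = config.effects
        report.recovery = {
            "beta_introgression_wild_dam": {
                "estimate": best.coefficient("introgression_wild_dam")[0],
                "truth": truth.beta_introgression_wild_dam,
            },
            "beta_dam_hatchery": {
                "estimate": best.coefficient("dam_hatchery")[0],
                "truth": truth.beta_dam_hatchery,
            },
            "smolt_pct_effect": {"estimate": pct[0], "truth": truth.smolt_pct_effect},
            "run_year_mean_hatchery": {
                "estimate": glmm.grand_mean_hatchery, "truth": truth.run_year_means[1]
            },
            "run_year_mean_wild": {
                "estimate": glmm.grand_mean_wild, "truth": truth.run_year_means[0]
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    return report
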