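#!/usr/bin/env python
"""Assign recaptured adults to broodstock pairs by Mendelian exclusion.

Scores every dam x sire combination in the offspring's brood year +/- 1,
accepts unique best pairs with at most two mismatches, verifies maternity
against mtDNA, and collapses assignments into the per-pair family table
used by the reproductive-success models.  Writes results/assignments.tsv
and results/families.tsv.
"""

import argparse
from pathlib import Path

from introgress_stock.io import read_genotypes, read_table, write_table
from introgress_stock.parentage import assign_all, build_family_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--ancestry", type=Path, default=Path("results/ancestry.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--max-mismatch", type=int, default=2)
    args = ap.parse_args()

    offspring = read_table(args.datadir / "offspring.tsv")
    assignments = assign_all(
        offspring,
        read_genotypes(args.datadir / "offspring_genotypes.tsv"),
        read_table(args.datadir / "broodstock.tsv"),
        read_genotypes(args.datadir / "broodstock_genotypes.tsv"),
        offspring_mt=read_genotypes(args.datadir / "offspring_mt.tsv"),
        roster_mt=read_genotypes(args.datadir / "broodstock_mt.tsv"),
        max_mismatch=args.max_mismatch,
    )
    write_table(assignments, args.outdir / "assignments.tsv")

    print(assignments["status"].value_counts().to_string())
    assigned = assignments[assignments["status"] == "assigned"]
    truth = offspring.set_index("individual_id")
    correct = (
        (assigned["dam_id"].to_numpy() == truth.loc[assigned["individual_id"], "dam_id"].to_numpy())
        & (assigned["sire_id"].to_numpy() == truth.loc[assigned["individual_id"], "sire_id"].to_numpy())
    )
    print(f"accuracy vs generator truth: {correct.mean():.4f}")
    print("mismatch counts:", assigned["mismatch_count"].value_counts().sort_index().to_dict())
    print("mt check:", assigned["mt_consistent"].value_counts().to_dict())

    brood = read_table(args.datadir / "broodstock.tsv")
    est = read_table(args.ancestry)
    info = brood[["individual_id", "hatchery"]].merge(
        est[["individual_id", "D"]], on="individual_id"
    )
    families = build_family_table(assignments, info)
    families = families.merge(
        read_table(args.datadir / "crosses_truth.tsv")[
            ["dam_id", "sire_id", "egg_number", "egg_size_ml", "dam_weight_g"]
        ],
        on=["dam_id", "sire_id"], how="left",
    )
    write_table(families, args.outdir / "families.tsv")
    print(f"{len(families)} families (mean size {families.n_offspring.mean():.1f}) "
          f"-> {args.outdir / 'families.tsv'}")


if __name__ == "__main__":
    main()
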