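# introgress-stock

Quantitative machinery for studying how hatchery supplementation interacts
with farmed-salmon introgression in wild Atlantic salmon (*Salmo salar*)
populations: per-individual farmed-ancestry estimation from diagnostic SNP
panels, parentage assignment of recaptured adults by Mendelian exclusion,
scale-based back-calculation of smolt size, and the mixed-effects model
suite relating broodstock ancestry to reproductive success — exercised
end-to-end on synthetic studies with known ground truth.

It is written for population geneticists and fisheries scientists who work
with stocked rivers where escaped farmed salmon hybridise with wild fish,
and who want a tested, reproducible implementation of this analysis chain
rather than one-off scripts.

## The models

**Farmed ancestry.** Each fish is genotyped at a nuclear SNP panel of which
a diagnostic subset shows large wild/farmed allele-frequency differences.
The farmed-membership probability *P*<sub>ind</sub> is the admixture
proportion *q* ∈ [0, 1] maximising the binomial log-likelihood
Σ<sub>loci</sub> [*g* ln *p* + (2 − *g*) ln(1 − *p*)] with
*p* = *q·f* + (1 − *q*)·*w* over non-missing diagnostic loci, where *g* is
the 0/1/2 dosage and *w*, *f* the wild and farmed reference frequencies.
It is rescaled to proportion farmed ancestry with the reference averages of
pure wild (*P*<sub>W</sub> = 0.0644) and farmed (*P*<sub>D</sub> = 0.903)
samples:

&nbsp;&nbsp;&nbsp;&nbsp;*D* = (*P*<sub>ind</sub> − *P*<sub>W</sub>) / (*P*<sub>D</sub> − *P*<sub>W</sub>)

**Parentage.** Offspring are matched against every dam × sire combination
of the broodstock used in their brood year ± 1; a locus is a Mendelian
mismatch when no pair of transmitted alleles can produce the offspring
genotype. A unique best pair with ≤ 2 mismatches is accepted; ties are
ambiguous; fish with > 20% missing calls are excluded. Maternity is
verified against the dam's 15-SNP mitochondrial haplotype.

**Reproductive success and eggs.** Per-pair recapture counts are analysed
as ln *N* with a brood-year random intercept, fitted by maximum likelihood
so AIC comparisons across fixed structures are valid; the reported models
are dam background + background-specific introgression slopes, with and
without ln(egg number). Egg size and egg number get analogous log-scale
mixed models. Effects are reported as factors with Wald 95% intervals
(estimate ± 1.96 SE, exponentiated).

**Growth and sea age.** Smolt length is back-calculated from scales by the
proportional body–scale (Lea-Dahl) relation *L*<sub>i</sub> =
(*S*<sub>i</sub>/*S*<sub>total</sub>)·*L*<sub>capture</sub> and modelled as
ln *L* with sea-age intercepts and an introgression slope. Sea age
(1, 2, 3+ winters) follows a multinomial-logit mixed model with two
log-odds contrasts against the 3+ baseline, within/among-year ancestry
decomposition and independent normal year effects integrated by a Laplace
approximation; the introgression effect is tested by a χ²(2) likelihood
ratio.

**Run-year contrasts.** Per-individual ancestry of returning adults is
modelled as logit(*P*<sub>ind,ij</sub>) = *a*<sub>i</sub> +
*b*<sub>i</sub>*H*<sub>ij</sub> + *e*<sub>ij</sub>, with year *i*, hatchery
indicator *H* and a normal observation-level effect *e* absorbing
overdispersion; per-year Wald tests of *b*<sub>i</sub> = 0 flag years with
a significant wild/hatchery difference.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_estimate_ancestry.py
python analysis/03_assign_parentage.py
python analysis/04_phenotypes.py
python analysis/05_fit_broodstock_models.py
python analysis/06_growth_and_sea_age.py
python analysis/07_run_year_introgression.py
```

Selected output of the chain:

```
panel: 81 nuclear (48 diagnostic), 15 mtDNA loci; calibrated P_W=0.0420, P_D=0.9566
broodstock pairs: 85; offspring recaptured as adults: 1000 (mean family size 11.8, range 2-42)
...
hatchery-origin broodstock: mean D = 0.285 (generating truth 0.303, n=109)
wild-origin broodstock: mean D = 0.126 (generating truth 0.127, n=61)
...
status
assigned    1000
accuracy vs generator truth: 1.0000
mismatch counts: {0: 936, 1: 64}
...
model selection (log recaptured offspring):
  best (+ log egg number): AIC 132.59 (delta 0.00)
  introgression + dam background: AIC 155.52 (delta 22.93)
...
grand mean proportion farmed ancestry: wild-born 0.097, hatchery-reared 0.260
hatchery > wild contrast significant in 20 of 20 run years (alpha 0.05)
```

Reading this: ancestry estimation recovers the generating group means
(0.285 vs truth 0.303; 0.126 vs 0.127); with the default 0.2% genotyping
error rate every offspring is still assigned to its true parents, 64 of
them carrying one tolerated mismatch; model selection prefers the count
model that controls for egg number; and hatchery-reared spawners carry
about 2.7× the farmed ancestry of wild-born ones across run years.

A `introgress-stock` command-line tool wraps the same steps
(`simulate`, `ancestry`, `assign`, `phenotypes`, `fit`, `run-all`), driven
by a YAML configuration; see `introgress-stock --help`.

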