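"""Independent brute-force oracles used across test modules."""

import numpy as np


def grid_search_q(genotypes, panel, n=10001):
    """Exhaustive grid oracle for the farmed-membership MLE."""
    g = np.asarray(genotypes, dtype=float)[panel.diagnostic]
    ok = ~np.isnan(g)
    g = g[ok]
    w = np.clip(panel.wild_freq[panel.diagnostic][ok], 1e-4, 1 - 1e-4)
    f = np.clip(panel.farmed_freq[panel.diagnostic][ok], 1e-4, 1 - 1e-4)
    qs = np.linspace(0, 1, n)
    p = qs[:, None] * f + (1 - qs[:, None]) * w
    ll = (g * np.log(p) + (2 - g) * np.log1p(-p)).sum(axis=1)
    return qs[np.argmax(ll)]


def brute_force_mismatches(off, dam, sire):
    """Oracle: enumerate the four transmitted-allele combinations per locus."""
    alleles = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    count = compared = 0
    for o, d, s in zip(off, dam, sire):
        if any(np.isnan(v) for v in (o, d, s)):
            continue
        compared += 1
        possible = {a + b for a in alleles[d] for b in alleles[s]}
        if o not in possible:
            count += 1
    return count, compared
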