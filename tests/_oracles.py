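"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (loops over samples and
loci, direct enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

MISSING = -1


def wc_components_one_locus(genotype_lists):
    """Weir & Cockerham (1984) variance components for one biallelic locus.

    ``genotype_lists`` is a list of per-population lists of dosages
    (0/1/2); returns (a, b, c) or None when the estimator is undefined.
    """
    r = len(genotype_lists)
    ns = [len(g) for g in genotype_lists]
    if any(n == 0 for n in ns):
        return None
    ps = [sum(g) / (2 * n) for g, n in zip(genotype_lists, ns)]
    hs = [sum(1 for x in g if x == 1) / n for g, n in zip(genotype_lists, ns)]
    n_total = sum(ns)
    n_bar = n_total / r
    if n_bar <= 1:
        return None
    nc = (n_total - sum(n * n for n in ns) / n_total) / (r - 1)
    if nc == 0:
        return None
    p_bar = sum(n * p for n, p in zip(ns, ps)) / n_total
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(ns, hs)) / n_total
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
    a = n_bar / nc * (s2 - inner / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def wc_fst_summaries(dosage, group_masks):
    """Mean-of-ratios and ratio-of-sums theta over loci, looped per locus."""
    n_samples, n_loci = dosage.shape
    thetas, sum_a, sum_d = [], 0.0, 0.0
    for j in range(n_loci):
        pops = []
        for mask in group_masks:
            pops.append(
                [int(dosage[i, j]) for i in range(n_samples) if mask[i] and dosage[i, j] != MISSING]
            )
        comp = wc_components_one_locus(pops)
        if comp is None:
            continue
        a, b, c = comp
        denom = a + b + c
        if denom == 0:
            continue
        thetas.append(a / denom)
        sum_a += a
        sum_d += denom
    mean = sum(thetas) / len(thetas) if thetas else float("nan")
    weighted = sum_a / sum_d if sum_d else float("nan")
    return mean, weighted, thetas


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by full enumeration of the hypergeometric.

    Table rows are (a, b) and (c, d); the p-value sums the probabilities of
    all tables with the same margins whose probability does not exceed the
    observed one (within a relative tolerance for float ties).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_prob(x):
        # P(X = x) for X ~ Hypergeometric(n, col1, row1)
        return (
            math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
            + math.lgamma(row2 + 1) - math.lgamma(col1 - x + 1)
            - math.lgamma(row2 - col1 + x + 1)
            + math.lgamma(col1 + 1) + math.lgamma(n - col1 + 1) - math.lgamma(n + 1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    observed = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= observed + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def brute_private(dosage, group_masks):
    """Per-locus (nonref_private, ref_private) flags by direct tallying."""
    n_samples, n_loci = dosage.shape
    out = []
    for j in range(n_loci):
        alt, ref = [0, 0], [0, 0]
        for gi, mask in enumerate(group_masks):
            for i in range(n_samples):
                if mask[i] and dosage[i, j] != MISSING:
                    alt[gi] += dosage[i, j]
                    ref[gi] += 2 - dosage[i, j]
        nonref = (alt[0] >= 1) != (alt[1] >= 1)
        refpriv = (ref[0] >= 1) != (ref[1] >= 1)
        out.append((nonref, refpriv))
    return out


def brute_region_segregating(dosage, west_mask, east_mask):
    """Indices of loci that segregate completely between two groups."""
    n_samples, n_loci = dosage.shape
    hits = []
    for j in range(n_loci):
        west = [dosage[i, j] for i in range(n_samples) if west_mask[i] and dosage[i, j] != MISSING]
        east = [dosage[i, j] for i in range(n_samples) if east_mask[i] and dosage[i, j] != MISSING]
        if not west or not east:
            continue
        if any(g == 1 for g in west + east):
            continue
        if len(set(west)) != 1 or len(set(east)) != 1:
            continue
        if west[0] != east[0]:
            hits.append(j)
    return hits


def brute_filter_survivors(dosage, depth, pl, n_samples, pl_min, min_depth,
                           min_fraction, min_alt, max_missing):
    """Survivor locus indices after the full filter chain, recomputed naively."""
    n, m = len(dosage), len(dosage[0])
    masked = [[None] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            g = dosage[i][j]
            if g == MISSING:
                masked[i][j] = MISSING
                continue
            triple = sorted(pl[i][j])
            masked[i][j] = g if triple[1] >= pl_min else MISSING
    survivors = []
    for j in range(m):
        covered = sum(1 for i in range(n) if depth[i][j] >= min_depth)
        if covered < math.ceil(min_fraction * n):
            continue
        alt = sum(masked[i][j] for i in range(n) if masked[i][j] != MISSING)
        if alt < min_alt:
            continue
        miss = sum(1 for i in range(n) if masked[i][j] == MISSING)
        if max_missing is not None and miss > max_missing:
            continue
        survivors.append(j)
    return survivors
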