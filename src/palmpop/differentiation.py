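"""Between-population differentiation statistics.

Given a two-group split of the samples (by default the Western-plus-Mixed
cultivars against the Eastern cultivars), this module counts alleles per
locus and group (heterozygotes contribute one copy of each allele), flags
private and fixed alleles, estimates Weir–Cockerham Fst from the variance
components a (among populations), b (among individuals within populations)
and c (within individuals), scans allele-frequency differences with a
two-sided Fisher exact test under Bonferroni correction, and summarises the
genomic distribution of the flagged SNPs on artificial chromosomes built
from a genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import UNMAPPED, GeneticMap
from .matrix import MISSING, GenotypeMatrix

#: Default two-group split: mixed cultivars side with the West.
DEFAULT_GROUPING = {"West": ["pop_1", "Mixed"], "East": ["pop_2"]}


def _group_members(labels, grouping: dict) -> dict[str, np.ndarray]:
    """Resolve a label->group mapping into per-group boolean sample masks."""
    labels = pd.Series(labels).reset_index(drop=True)
    if len(grouping) != 2:
        raise ValueError("grouping must define exactly two groups")
    masks = {}
    for group, members in grouping.items():
        mask = labels.isin(list(members)).to_numpy()
        if not mask.any():
            raise ValueError(f"group {group!r} has no samples")
        masks[group] = mask
    return masks


@dataclass
class AlleleCounts:
    """Per-locus, per-group allele and missing-genotype counts."""

    groups: list[str]
    ref: np.ndarray  # (2, L) reference-allele counts
    alt: np.ndarray  # (2, L) alternative-allele counts
    missing: np.ndarray  # (2, L) missing genotype counts
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def called_alleles(self) -> np.ndarray:
        return self.ref + self.alt


def allele_counts(gm: GenotypeMatrix, labels, grouping=None) -> AlleleCounts:
    """Count ref and alt alleles per locus in each of two groups.

    A heterozygote contributes one allele to each count, a homozygote two
    to one count; missing genotypes contribute nothing (tallied apart).
    """
    grouping = grouping or DEFAULT_GROUPING
    masks = _group_members(labels, grouping)
    groups = list(masks)
    L = gm.n_loci
    ref = np.zeros((2, L), dtype=np.int64)
    alt = np.zeros((2, L), dtype=np.int64)
    miss = np.zeros((2, L), dtype=np.int64)
    for gi, group in enumerate(groups):
        d = gm.dosage[masks[group]]
        called = d != MISSING
        alt[gi] = np.where(called, d, 0).sum(axis=0)
        ref[gi] = np.where(called, 2 - d, 0).sum(axis=0)
        miss[gi] = (~called).sum(axis=0)
    return AlleleCounts(groups=groups, ref=ref, alt=alt, missing=miss, loci=gm.loci)


# -- private alleles ---------------------------------------------------------


def private_alleles(counts: AlleleCounts) -> pd.DataFrame:
    """Flag loci where an allele occurs in exactly one group.

    The headline category is nonreference-private: the alternative allele
    present in one group and absent from the other. Reference-private loci
    (reference allele confined to one group) are tracked separately. No
    call-rate or frequency filters are applied.
    """
    alt0, alt1 = counts.alt
    ref0, ref1 = counts.ref
    out = pd.DataFrame(index=range(alt0.shape[0]))
    out["nonref_private"] = (alt0 >= 1) ^ (alt1 >= 1)
    out["nonref_private_group"] = np.select(
        [(alt0 >= 1) & (alt1 == 0), (alt1 >= 1) & (alt0 == 0)],
        [counts.groups[0], counts.groups[1]],
        default="",
    )
    out["ref_private"] = (ref0 >= 1) ^ (ref1 >= 1)
    out["ref_private_group"] = np.select(
        [(ref0 >= 1) & (ref1 == 0), (ref1 >= 1) & (ref0 == 0)],
        [counts.groups[0], counts.groups[1]],
        default="",
    )
    return out


def private_allele_summary(flags: pd.DataFrame, groups: list[str]) -> dict:
    n = len(flags)
    per_group = {
        g: int((flags["nonref_private_group"] == g).sum()) for g in groups
    }
    total = int(flags["nonref_private"].sum())
    return {
        "n_positions": n,
        "nonref_private_total": total,
        "nonref_private_fraction": total / n if n else float("nan"),
        "nonref_private_by_group": per_group,
        "ref_private_total": int(flags["ref_private"].sum()),
    }


# -- Weir-Cockerham Fst ------------------------------------------------------


@dataclass
class FstResult:
    """Per-locus Weir–Cockerham variance components and the two summaries.

    ``mean_fst`` averages per-locus a/(a+b+c) over loci with a nonzero
    denominator (negative estimates retained); ``weighted_fst`` is the
    ratio of sums over the same loci.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_locus: np.ndarray  # theta per locus; NaN where excluded
    informative: np.ndarray  # bool mask of loci entering the summaries
    mean_fst: float
    weighted_fst: float
    n_excluded: int


def weir_cockerham_fst(gm: GenotypeMatrix, labels, grouping=None) -> FstResult:
    """Weir–Cockerham (1984) theta for diploid biallelic loci.

    Components are computed from genotype counts (sample sizes, allele
    frequencies and observed heterozygosity per group), so within-individual
    information enters through c. Loci where any group has no called
    genotype, or where the total denominator a+b+c is zero (monomorphic
    sites), are excluded from both summaries and counted.
    """
    grouping = grouping or DEFAULT_GROUPING
    masks = _group_members(labels, grouping)
    r = len(masks)
    L = gm.n_loci
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for gi, mask in enumerate(masks.values()):
        d = gm.dosage[mask]
        called = d != MISSING
        n = called.sum(axis=0)
        n_i[gi] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[gi] = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            h_i[gi] = (d == 1).sum(axis=0) / n

    usable = (n_i >= 1).all(axis=0)
    n_bar = n_i.mean(axis=0)
    n_tot = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0
        a = n_bar / nc * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    # estimator undefined when n_bar == 1 or nc == 0 (all samples in one group)
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = a + b + c
    informative = usable & (denom != 0)
    if not informative.any():
        raise ValueError("no informative loci for Fst")
    theta = np.full(L, np.nan)
    theta[informative] = a[informative] / denom[informative]
    a_ = np.where(usable, a, np.nan)
    b_ = np.where(usable, b, np.nan)
    c_ = np.where(usable, c, np.nan)
    return FstResult(
        a=a_, b=b_, c=c_, per_locus=theta, informative=informative,
        mean_fst=float(np.nanmean(theta)),
        weighted_fst=float(a[informative].sum() / denom[informative].sum()),
        n_excluded=int((~informative).sum()),
    )


# -- Fisher exact allele-frequency scan --------------------------------------


def fisher_scan(counts: AlleleCounts, alpha: float = 0.01) -> pd.DataFrame:
    """Two-sided Fisher exact test on (ref, alt) x group allele counts.

    A locus is tested when both groups have at least one called allele;
    untested loci are excluded from the Bonferroni denominator m.
    p_adj = min(1, p * m); significant iff p_adj < alpha.
    """
    called = counts.called_alleles
    tested = (called >= 1).all(axis=0)
    m = int(tested.sum())
    L = called.shape[1]
    p = np.full(L, np.nan)
    for j in np.flatnonzero(tested):
        table = [
            [int(counts.ref[0, j]), int(counts.alt[0, j])],
            [int(counts.ref[1, j]), int(counts.alt[1, j])],
        ]
        p[j] = stats.fisher_exact(table, alternative="two-sided")[1]
    p_adj = np.minimum(1.0, p * m)
    return pd.DataFrame(
        {
            "tested": tested,
            "p": p,
            "p_adj": p_adj,
            "significant": tested & (p_adj < alpha),
        }
    )


# -- fixed differences -------------------------------------------------------


def fixed_differences(counts: AlleleCounts) -> np.ndarray:
    """Loci where the two groups are monomorphic for different alleles.

    Requires at least one called allele in each group; assessed over called
    alleles only.
    """
    alt0, alt1 = counts.alt
    ref0, ref1 = counts.ref
    tested = ((alt0 + ref0) >= 1) & ((alt1 + ref1) >= 1)
    way1 = (ref0 == 0) & (alt1 == 0)  # group 0 fixed alt, group 1 fixed ref
    way2 = (alt0 == 0) & (ref1 == 0)
    return tested & (way1 | way2)


# -- combined per-locus table ------------------------------------------------


def differentiation_table(
    gm: GenotypeMatrix, labels, grouping=None, alpha: float = 0.01
) -> tuple[pd.DataFrame, AlleleCounts]:
    """Assemble the per-locus differentiation table (counts, flags, p-values)."""
    grouping = grouping or DEFAULT_GROUPING
    counts = allele_counts(gm, labels, grouping)
    g0, g1 = counts.groups
    table = gm.loci.copy()
    table[f"ref_{g0}"], table[f"ref_{g1}"] = counts.ref
    table[f"alt_{g0}"], table[f"alt_{g1}"] = counts.alt
    table = pd.concat([table, private_alleles(counts)], axis=1)
    table["fixed"] = fixed_differences(counts)
    table = pd.concat([table, fisher_scan(counts, alpha=alpha)], axis=1)
    return table, counts


# -- genomic distribution ----------------------------------------------------


def build_artificial_chromosomes(gmap: GeneticMap, loci: pd.DataFrame) -> pd.DataFrame:
    """Transform contig:pos to (lg, artificial position) per the map order."""
    return gmap.locate_frame(loci)


def lg_enrichment(
    table: pd.DataFrame, gmap: GeneticMap, flag: str = "significant"
) -> pd.DataFrame:
    """Per-linkage-group enrichment of flagged SNPs over the genome average.

    fold = (flagged/total on the LG) / (flagged/total genome-wide); an LG
    with no flagged SNPs has fold 0.
    """
    coords = build_artificial_chromosomes(gmap, table)
    flagged = table[flag].fillna(False).astype(bool).to_numpy()
    genome_prop = flagged.mean() if len(table) else float("nan")
    rows = []
    for lg in list(gmap.linkage_groups) + [UNMAPPED]:
        on_lg = (coords["lg"] == lg).to_numpy()
        n = int(on_lg.sum())
        if n == 0 and lg == UNMAPPED:
            continue
        k = int(flagged[on_lg].sum())
        prop = k / n if n else float("nan")
        fold = prop / genome_prop if (n and genome_prop > 0) else 0.0 if n else float("nan")
        rows.append(
            {"lg": lg, "n_snps": n, "n_flagged": k, "proportion": prop, "fold": fold}
        )
    return pd.DataFrame(rows)


def window_density(
    table: pd.DataFrame,
    gmap: GeneticMap,
    window_bp: int,
    flags: tuple[str, ...] = ("nonref_private", "fixed", "significant"),
) -> pd.DataFrame:
    """Counts of flagged SNPs in half-open windows on artificial chromosomes."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    coords = build_artificial_chromosomes(gmap, table)
    df = coords.assign(
        **{f: table[f].fillna(False).astype(bool).to_numpy() for f in flags}
    )
    df["window_start"] = (df["artificial_pos"] // window_bp) * window_bp
    agg = (
        df.groupby(["lg", "window_start"], sort=True)
        .agg(n_snps=("artificial_pos", "size"), **{f: (f, "sum") for f in flags})
        .reset_index()
    )
    return agg


def exclude_lg(gm: GenotypeMatrix, gmap: GeneticMap, lg_id) -> GenotypeMatrix:
    """Drop all loci on contigs assigned to one linkage group."""
    if lg_id not in set(gmap.linkage_groups):
        raise ValueError(f"unknown linkage group {lg_id!r}")
    contigs = set(gmap.contigs_of(lg_id))
    keep = ~gm.loci["contig"].isin(contigs).to_numpy()
    return gm.take_loci(keep)
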