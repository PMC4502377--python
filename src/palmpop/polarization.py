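"""Outgroup polarization of region-segregating SNPs.

SNPs that segregate completely between the two cultivar groups (every
called Western genotype homozygous for one allele, every called Eastern
genotype homozygous for the other) are compared with the allele of a
distant outgroup genome (oil palm, here supplied as a precomputed table).
Each such SNP is classed by which population departed from the ancestral
state: east_deviated (West retains the outgroup allele), west_deviated,
both_deviated (outgroup carries a third allele), or unaligned when no
outgroup allele could be determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .report import round_half_away

UNALIGNED = "unaligned"

CLASSES = ("east_deviated", "west_deviated", "both_deviated", "unaligned")


def region_segregating(
    gm: GenotypeMatrix, labels, west_group=("pop_1", "Mixed"), east_group=("pop_2",)
) -> pd.DataFrame:
    """Find loci segregating completely between the two groups.

    A locus qualifies when every called Western genotype is homozygous for
    one allele, every called Eastern genotype is homozygous for the other,
    and each group has at least one call; any heterozygote disqualifies.
    Returns the qualifying loci with their fixed west/east alleles (bases).
    """
    labels = pd.Series(labels).reset_index(drop=True)
    west = labels.isin(list(west_group)).to_numpy()
    east = labels.isin(list(east_group)).to_numpy()
    if not west.any() or not east.any():
        raise ValueError("both groups need at least one sample")

    ref = gm.loci["ref"].to_numpy()
    alt = gm.loci["alt"].to_numpy()
    dw = gm.dosage[west]
    de = gm.dosage[east]
    cw = dw != MISSING
    ce = de != MISSING

    def fixed_allele(d, c):
        """Per locus: 0 (all hom-ref), 2 (all hom-alt) or -9 otherwise."""
        any_called = c.any(axis=0)
        has_het = ((d == 1) & c).any(axis=0)
        has_ref = ((d == 0) & c).any(axis=0)
        has_alt = ((d == 2) & c).any(axis=0)
        out = np.full(d.shape[1], -9)
        out[any_called & ~has_het & has_ref & ~has_alt] = 0
        out[any_called & ~has_het & has_alt & ~has_ref] = 2
        return out

    fw = fixed_allele(dw, cw)
    fe = fixed_allele(de, ce)
    qualifies = (fw >= 0) & (fe >= 0) & (fw != fe)
    idx = np.flatnonzero(qualifies)
    out = gm.loci.iloc[idx].copy()
    out["west_allele"] = np.where(fw[idx] == 0, ref[idx], alt[idx])
    out["east_allele"] = np.where(fe[idx] == 0, ref[idx], alt[idx])
    out["locus_index"] = idx
    return out.reset_index(drop=True)


@dataclass
class PolarizationSummary:
    records: pd.DataFrame
    per_scaffold: pd.DataFrame


def classify_polarization(seg: pd.DataFrame, ancestral: pd.DataFrame) -> PolarizationSummary:
    """Class each segregating SNP by which population left the ancestral allele.

    ``ancestral`` maps (contig, pos) to the outgroup base or ``"unaligned"``.
    east_deviated: west allele equals the ancestral allele (East changed);
    west_deviated: symmetric; both_deviated: the ancestral base matches
    neither allele; unaligned: no ancestral call. Per-scaffold percentages
    are rounded half-away-from-zero to integers.
    """
    anc = {
        (c, int(p)): a
        for c, p, a in zip(ancestral["contig"], ancestral["pos"], ancestral["allele"])
    }
    classes = []
    for row in seg.itertuples(index=False):
        allele = anc.get((row.contig, int(row.pos)), UNALIGNED)
        if allele == UNALIGNED or allele in ("", None):
            cls = "unaligned"
        elif allele == row.west_allele:
            cls = "east_deviated"
        elif allele == row.east_allele:
            cls = "west_deviated"
        else:
            cls = "both_deviated"
        classes.append(cls)
    records = seg.copy()
    records["class"] = classes

    rows = []
    for scaffold, grp in records.groupby("contig", sort=True):
        n = len(grp)
        entry = {"scaffold": scaffold, "n_segregating": n}
        for cls in CLASSES:
            k = int((grp["class"] == cls).sum())
            entry[f"n_{cls}"] = k
            entry[f"pct_{cls}"] = round_half_away(100.0 * k / n)
        rows.append(entry)
    per_scaffold = pd.DataFrame(
        rows,
        columns=["scaffold", "n_segregating"]
        + [f"n_{c}" for c in CLASSES]
        + [f"pct_{c}" for c in CLASSES],
    )
    return PolarizationSummary(records=records, per_scaffold=per_scaffold)
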