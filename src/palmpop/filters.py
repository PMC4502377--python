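"""Genotype quality and missingness filters for GBS SNP matrices.

The filters reproduce a stringent GBS post-calling protocol: genotype calls
whose second-smallest PL (the confidence margin of the best call) falls below
a phred threshold are set missing; sites must reach a minimum depth in a
minimum fraction of individuals; alternative alleles must be observed a
minimum number of times among called genotypes; and sites with too many
missing genotypes are dropped. Duplicate-sample concordance converts observed
agreement between technical replicates into a predicted per-sample genotyping
accuracy under the assumption that errors are equally likely in both members
of a pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, PL_MISSING, GenotypeMatrix


@dataclass
class FilterReport:
    """Per-rule tally of removed loci or masked cells, in application order."""

    stages: list[dict] = field(default_factory=list)

    def add(self, rule: str, kind: str, n_input: int, n_removed: int, **params) -> None:
        self.stages.append(
            {
                "rule": rule,
                "kind": kind,  # "loci" or "cells"
                "n_input": n_input,
                "n_removed": n_removed,
                "n_surviving": n_input - n_removed,
                **params,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mask_low_confidence(
    gm: GenotypeMatrix, pl_min: int = 35, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Set calls whose secondary PL is below ``pl_min`` to missing.

    The secondary call is the second-smallest value of the PL triple; it is
    the phred-scaled margin by which the best genotype beats the runner-up.
    Calls with no PL available are also set missing (and counted).
    """
    report = report or FilterReport()
    out = gm.copy()
    called = out.called
    if out.pl is None:
        n_masked = int(called.sum())
        out.dosage[called] = MISSING
    else:
        second = np.sort(out.pl, axis=2)[:, :, 1]
        no_pl = (out.pl == PL_MISSING).any(axis=2)
        bad = called & (no_pl | (second < pl_min))
        n_masked = int(bad.sum())
        out.dosage[bad] = MISSING
    report.add(
        "mask_low_confidence", "cells", int(called.sum()), n_masked, pl_min=pl_min
    )
    return out, report


def filter_site_coverage(
    gm: GenotypeMatrix,
    min_depth: int = 10,
    min_fraction: float = 0.8,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci with depth >= ``min_depth`` in at least ``min_fraction`` of samples.

    The required count is ``ceil(min_fraction * n_samples)``, so a site
    covered in exactly the threshold fraction passes.
    """
    report = report or FilterReport()
    need = math.ceil(min_fraction * gm.n_samples)
    keep = (gm.depth >= min_depth).sum(axis=0) >= need
    report.add(
        "filter_site_coverage", "loci", gm.n_loci, int((~keep).sum()),
        min_depth=min_depth, min_fraction=min_fraction,
    )
    return gm.take_loci(keep), report


def filter_alt_support(
    gm: GenotypeMatrix, min_alt_obs: int = 4, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci whose alternative allele is observed >= ``min_alt_obs`` times.

    Observations are counted over called genotypes: a heterozygote
    contributes one, a homozygous-alternative call two.
    """
    report = report or FilterReport()
    alt = np.where(gm.called, gm.dosage, 0).sum(axis=0)
    keep = alt >= min_alt_obs
    report.add(
        "filter_alt_support", "loci", gm.n_loci, int((~keep).sum()),
        min_alt_obs=min_alt_obs,
    )
    return gm.take_loci(keep), report


def filter_max_missing(
    gm: GenotypeMatrix, max_missing: int, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci with at most ``max_missing`` missing genotype calls."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    report = report or FilterReport()
    n_missing = (~gm.called).sum(axis=0)
    keep = n_missing <= max_missing
    report.add(
        "filter_max_missing", "loci", gm.n_loci, int((~keep).sum()),
        max_missing=max_missing,
    )
    return gm.take_loci(keep), report


def apply_standard_filters(
    gm: GenotypeMatrix,
    pl_min: int = 35,
    min_depth: int = 10,
    min_fraction: float = 0.8,
    min_alt_obs: int = 4,
    max_missing: int | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full filter chain: PL mask -> coverage -> alt support -> missingness."""
    report = FilterReport()
    gm, _ = mask_low_confidence(gm, pl_min, report)
    gm, _ = filter_site_coverage(gm, min_depth, min_fraction, report)
    gm, _ = filter_alt_support(gm, min_alt_obs, report)
    if max_missing is not None:
        gm, _ = filter_max_missing(gm, max_missing, report)
    return gm, report


def duplicate_concordance(
    gm: GenotypeMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Genotype concordance between technical-replicate sample pairs.

    For each pair, concordance is the fraction of loci called in both
    members where the calls agree. Under the model that genotyping errors
    are equally likely in either member, the per-sample accuracy is
    ``1 - (1 - concordance) / 2``. Pairs with no co-called loci are reported
    with ``n_compared = 0`` and NaN metrics.
    """
    rows = []
    for a, b in pairs:
        ia, ib = gm.sample_index([a, b])
        da, db = gm.dosage[ia], gm.dosage[ib]
        both = (da != MISSING) & (db != MISSING)
        n = int(both.sum())
        if n == 0:
            conc = acc = float("nan")
        else:
            conc = float((da[both] == db[both]).mean())
            acc = 1.0 - (1.0 - conc) / 2.0
        rows.append(
            {
                "sample_a": a, "sample_b": b, "n_compared": n,
                "concordance": conc, "predicted_accuracy": acc,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_compared", "concordance", "predicted_accuracy"]
    )
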