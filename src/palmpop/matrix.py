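"""In-memory container for a multi-sample biallelic SNV genotype matrix.

The matrix is samples x loci with, per cell, an allele dosage (number of
copies of the alternative allele: 0, 1, 2, or missing), a read depth, and a
phred-scaled genotype-likelihood (PL) triple in the SAMtools/BCFtools
convention (ordered hom-ref, het, hom-alt; minimum rescaled to 0 for called
genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING = -1

#: Sentinel for an unavailable PL triple.
PL_MISSING = -1

LOCUS_COLUMNS = ("contig", "pos", "ref", "alt")

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Locus:
    """A biallelic single-nucleotide variant site (1-based VCF position)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"non-SNV alleles {self.ref}/{self.alt} at {self.contig}:{self.pos}"
            )


class GenotypeMatrix:
    """Samples x biallelic-loci genotype matrix with depth and PL layers.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    loci
        DataFrame with columns ``contig, pos, ref, alt`` (one row per locus,
        in matrix column order).
    dosage
        int array (n_samples, n_loci); entries in {0, 1, 2} or ``MISSING``.
    depth
        int array (n_samples, n_loci); reads covering the site (0 if unknown).
    pl
        int array (n_samples, n_loci, 3) of phred-scaled likelihoods, or
        ``PL_MISSING`` where unavailable. May be None if the source VCF
        carried no PL field.
    """

    def __init__(
        self,
        samples: list[str],
        loci: pd.DataFrame,
        dosage: np.ndarray,
        depth: np.ndarray | None = None,
        pl: np.ndarray | None = None,
    ):
        self.samples = list(samples)
        self.loci = loci.reset_index(drop=True)
        if list(self.loci.columns[:4]) != list(LOCUS_COLUMNS):
            raise ValueError(f"loci must have columns {LOCUS_COLUMNS}")
        dosage = np.asarray(dosage, dtype=np.int8)
        n, m = len(self.samples), len(self.loci)
        if dosage.shape != (n, m):
            raise ValueError(f"dosage shape {dosage.shape} != ({n}, {m})")
        self.dosage = dosage
        self.depth = (
            np.zeros((n, m), dtype=np.int32)
            if depth is None
            else np.asarray(depth, dtype=np.int32)
        )
        if self.depth.shape != (n, m):
            raise ValueError("depth shape mismatch")
        self.pl = None if pl is None else np.asarray(pl, dtype=np.int32)
        if self.pl is not None and self.pl.shape != (n, m, 3):
            raise ValueError("pl shape mismatch")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosage != MISSING

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    # -- subsetting ----------------------------------------------------------

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.loci,
            self.dosage[idx],
            self.depth[idx],
            None if self.pl is None else self.pl[idx],
        )

    def take_loci(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.samples,
            self.loci.iloc[idx],
            self.dosage[:, idx],
            self.depth[:, idx],
            None if self.pl is None else self.pl[:, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.loci.copy(),
            self.dosage.copy(),
            self.depth.copy(),
            None if self.pl is None else self.pl.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci, "
            f"PL={'yes' if self.pl is not None else 'no'})"
        )


@dataclass
class SampleSheet:
    """Sample metadata: claimed region, species flag, duplicate provenance."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample", "region", "species", "duplicate_of")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def duplicate_pairs(self) -> list[tuple[str, str]]:
        dup = self.table[self.table["duplicate_of"].notna() & (self.table["duplicate_of"] != "")]
        return [(row["duplicate_of"], row["sample"]) for _, row in dup.iterrows()]

    def ingroup_samples(self, species: str = "P_dactylifera") -> list[str]:
        return list(self.table.loc[self.table["species"] == species, "sample"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        tab = pd.read_csv(path, sep="\t", dtype=str).fillna({"duplicate_of": ""})
        return cls(tab)
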