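"""Genetic map: ordered contigs per linkage group and artificial chromosomes.

Unanchored assembly contigs are concatenated in genetic-map order to form one
artificial chromosome per linkage group (LG), giving map-scale coordinates
for density and enrichment plots. A contig's offset is the cumulative length
of the contigs preceding it within its LG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNMAPPED = "unmapped"


class GeneticMap:
    """Ordered (linkage group, contig, order, length) records.

    Parameters
    ----------
    table
        DataFrame with columns ``lg, contig, order, length``; ``(lg, order)``
        pairs must be unique and each contig may appear once.
    """

    COLUMNS = ("lg", "contig", "order", "length")

    def __init__(self, table: pd.DataFrame):
        for col in self.COLUMNS:
            if col not in table.columns:
                raise ValueError(f"genetic map missing column {col!r}")
        table = table.sort_values(["lg", "order"]).reset_index(drop=True)
        if table.duplicated(subset=["lg", "order"]).any():
            raise ValueError("duplicate (lg, order) in genetic map")
        if table["contig"].duplicated().any():
            dup = table.loc[table["contig"].duplicated(), "contig"].iloc[0]
            raise ValueError(f"contig {dup!r} appears more than once in map")
        offsets = table.groupby("lg", sort=False)["length"].cumsum() - table["length"]
        table = table.assign(offset=offsets)
        self.table = table
        self._contig_row = {
            row.contig: (row.lg, int(row.offset)) for row in table.itertuples()
        }

    @property
    def linkage_groups(self) -> list:
        return list(dict.fromkeys(self.table["lg"]))

    def contigs_of(self, lg) -> list[str]:
        return list(self.table.loc[self.table["lg"] == lg, "contig"])

    def locate(self, contig: str, pos: int) -> tuple:
        """Map contig:pos to (lg, artificial position); unmapped contigs
        route to the ``"unmapped"`` bucket with their original position."""
        hit = self._contig_row.get(contig)
        if hit is None:
            return UNMAPPED, pos
        lg, offset = hit
        return lg, offset + pos

    def locate_frame(self, loci: pd.DataFrame) -> pd.DataFrame:
        """Vectorised :meth:`locate` over a loci frame (contig, pos columns)."""
        lgs = np.empty(len(loci), dtype=object)
        apos = np.empty(len(loci), dtype=np.int64)
        for i, (contig, pos) in enumerate(zip(loci["contig"], loci["pos"])):
            lgs[i], apos[i] = self.locate(contig, int(pos))
        return pd.DataFrame({"lg": lgs, "artificial_pos": apos}, index=loci.index)

    def to_tsv(self, path) -> None:
        self.table[list(self.COLUMNS)].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))
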