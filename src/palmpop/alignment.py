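"""Concatenated-SNP alignments and pairwise distances for tree building.

Genotypes are concatenated into one character per locus per sample. In
``homozygous`` mode only homozygous calls are informative (heterozygotes
and missing calls become N), matching topology inference restricted to
homozygous SNPs; ``iupac`` mode encodes heterozygotes with two-base
ambiguity codes. Output formats are FASTA and relaxed PHYLIP; tree search
itself is left to external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import MISSING, GenotypeMatrix

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_AMBIGUOUS = set("RYSWKMN")


@dataclass
class SnpAlignment:
    names: list[str]
    sequences: list[str]  # equal length; column i <-> locus i

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n{seq}\n")

    def write_phylip(self, path) -> None:
        """Relaxed PHYLIP: names of any length, one space before the sequence."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)} {self.n_sites}\n")
            width = max(len(n) for n in self.names)
            for name, seq in zip(self.names, self.sequences):
                fh.write(f"{name.ljust(width)} {seq}\n")

    @classmethod
    def read_fasta(cls, path) -> "SnpAlignment":
        names, seqs, cur = [], [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith(">"):
                if names:
                    seqs.append("".join(cur))
                names.append(line[1:].strip())
                cur = []
            elif line.strip():
                cur.append(line.strip())
        if names:
            seqs.append("".join(cur))
        return cls(names, seqs)

    @classmethod
    def read_phylip(cls, path) -> "SnpAlignment":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        names, seqs = [], []
        for ln in lines[1:]:
            name, seq = ln.split(None, 1)
            names.append(name)
            seqs.append(seq.replace(" ", ""))
        return cls(names, seqs)


def export_alignment(gm: GenotypeMatrix, mode: str = "homozygous") -> SnpAlignment:
    """Concatenate SNP genotypes into per-sample sequences.

    homozygous mode: dosage 0 -> ref base, 2 -> alt base, het/missing -> N.
    iupac mode: heterozygotes become the two-base ambiguity code.
    """
    if mode not in ("homozygous", "iupac"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = gm.loci["ref"].to_numpy()
    alt = gm.loci["alt"].to_numpy()
    het = np.array(
        [IUPAC[frozenset((r, a))] if mode == "iupac" else "N" for r, a in zip(ref, alt)]
    )
    seqs = []
    for i in range(gm.n_samples):
        d = gm.dosage[i]
        chars = np.where(d == 0, ref, np.where(d == 2, alt, np.where(d == 1, het, "N")))
        seqs.append("".join(chars))
    return SnpAlignment(list(gm.samples), seqs)


def bootstrap_alignment(aln: SnpAlignment, seed=None) -> SnpAlignment:
    """Resample alignment columns with replacement (seeded)."""
    rng = np.random.default_rng(seed)
    m = aln.n_sites
    cols = rng.integers(0, m, size=m)
    seqs = ["".join(seq[j] for j in cols) for seq in aln.sequences]
    return SnpAlignment(list(aln.names), seqs)


def pairwise_distances(aln: SnpAlignment):
    """Pairwise p-distances ignoring N/ambiguous positions.

    Returns (distance matrix, comparable-site matrix); pairs with zero
    comparable sites get NaN distance.
    """
    if len(aln.names) < 2:
        raise ValueError("need at least two sequences")
    arr = np.array([list(s) for s in aln.sequences])
    ok = ~np.isin(arr, list(_AMBIGUOUS))
    n = len(aln.names)
    dist = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            comparable[i, j] = comparable[j, i] = m
            d = float((arr[i, both] != arr[j, both]).mean()) if m else float("nan")
            dist[i, j] = dist[j, i] = d
    comparable[np.diag_indices(n)] = ok.sum(axis=1)
    return dist, comparable
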