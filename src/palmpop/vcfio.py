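"""Reading and writing multi-sample VCF 4.2 with GT:DP:PL genotypes.

Reading uses cyvcf2 (htslib). Only biallelic single-nucleotide records are
retained; indels and multi-allelic records are dropped and counted. Writing
emits plain text deterministically so that identical matrices produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, PL_MISSING, GenotypeMatrix

_SNV = frozenset("ACGT")


@dataclass
class ReadReport:
    """Records dropped during VCF import, by reason."""

    n_kept: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_indel + self.n_multiallelic


def read_vcf(path, return_report: bool = False):
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Indels (REF or ALT longer than one base, or symbolic) and records with
    more than one ALT allele are dropped and tallied in the report. Sample
    and record order is preserved. DP and PL are optional; absent DP is
    treated as depth 0 and absent PL as unavailable.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path!r} contains no samples")

    report = ReadReport()
    loci_rows = []
    dosage_cols, depth_cols, pl_cols = [], [], []
    any_pl = False

    for var in vcf:
        alts = var.ALT
        if len(alts) != 1:
            report.n_multiallelic += 1
            continue
        ref, alt = var.REF, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _SNV or alt not in _SNV:
            report.n_indel += 1
            continue
        report.n_kept += 1
        loci_rows.append((var.CHROM, var.POS, ref, alt))

        gts = np.asarray([g[:2] for g in var.genotypes], dtype=np.int64)
        dos = gts.sum(axis=1).astype(np.int8)
        dos[(gts < 0).any(axis=1)] = MISSING
        dosage_cols.append(dos)

        dp = var.format("DP")
        if dp is None:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
        else:
            dp = dp.reshape(len(samples)).astype(np.int64)
            dp[dp < 0] = 0
            depth_cols.append(dp.astype(np.int32))

        pl = var.format("PL")
        if pl is None:
            pl_cols.append(np.full((len(samples), 3), PL_MISSING, dtype=np.int32))
        else:
            any_pl = True
            pl = pl.astype(np.int64)
            if pl.shape != (len(samples), 3):
                pl = np.full((len(samples), 3), PL_MISSING, dtype=np.int64)
            pl[pl < 0] = PL_MISSING
            pl_cols.append(pl.astype(np.int32))

    n, m = len(samples), len(loci_rows)
    loci = pd.DataFrame(loci_rows, columns=["contig", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosage_cols, axis=1) if m else np.zeros((n, 0), dtype=np.int8)
    )
    depth = np.stack(depth_cols, axis=1) if m else np.zeros((n, 0), dtype=np.int32)
    pl = np.stack(pl_cols, axis=1) if (m and any_pl) else None
    gm = GenotypeMatrix(samples, loci, dosage, depth, pl)
    return (gm, report) if return_report else gm


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    Emits GT:DP:PL (GT:DP when the matrix has no PL layer). Contig header
    lines appear in first-seen locus order, so the output is a deterministic
    function of the matrix.
    """
    path = Path(path)
    contigs = list(dict.fromkeys(gm.loci["contig"]))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=palmpop",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of called samples">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples)
    )

    has_pl = gm.pl is not None
    fmt = "GT:DP:PL" if has_pl else "GT:DP"
    dosage, depth, pl = gm.dosage, gm.depth, gm.pl
    for j, row in enumerate(gm.loci.itertuples(index=False)):
        ns = int((dosage[:, j] != MISSING).sum())
        fields = [
            str(row.contig), str(row.pos), ".", row.ref, row.alt, ".", "PASS",
            f"NS={ns}", fmt,
        ]
        for i in range(gm.n_samples):
            cell = f"{_GT_STR[int(dosage[i, j])]}:{int(depth[i, j])}"
            if has_pl:
                trip = pl[i, j]
                cell += ":" + (
                    "."
                    if (trip == PL_MISSING).any()
                    else ",".join(str(int(v)) for v in trip)
                )
            fields.append(cell)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
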