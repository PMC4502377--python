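"""Synthetic two-population GBS dataset generator with ground truth.

The generator emulates the sampling design of a cultivar survey: two diverged
source populations (West/East) at a chosen divergence F under the
Balding–Nichols model, a set of admixed individuals, a small outgroup of
related species, per-call read depth and phred-scaled genotype likelihoods,
random missingness, and technical-replicate (duplicate) samples with an
independent per-call error rate. Every randomised quantity derives from a
single seed, so identical configurations produce byte-identical outputs.

Under Balding–Nichols, each locus has an ancestral frequency p and each
population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F); F is then
the expected Weir–Cockerham Fst between the populations, which gives the
downstream estimators a known recovery target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .matrix import MISSING, GenotypeMatrix, SampleSheet

#: Sequencing error used for read draws and PL likelihoods.
READ_ERROR = 0.01

UNALIGNED = "unaligned"

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic survey.

    Counts mirror the emulated study design: 11 Western + 52 Eastern
    cultivars, 7 admixed, 4 outgroup trees, 4 duplicated samples. The
    divergence default (0.267) is the weighted between-region Fst the
    design targets; the duplicate error rate (0.006) corresponds to a
    predicted per-sample genotyping accuracy of 99.4% under the
    equal-error model.
    """

    n_loci: int = 2000
    n_per_pop: tuple[int, int] = (11, 52)  # (West, East)
    n_admixed: int = 7
    admix_q: float = 0.5  # expected Western ancestry of admixed samples
    fst_true: float = 0.267
    n_outgroup: int = 4
    outgroup_divergence: float = 0.6
    private_rate: float = 0.02
    mean_depth: float = 20.0
    missing_rate: float = 0.05
    genotype_error: float = 0.006
    n_duplicates: int = 4
    n_contigs: int = 40
    n_lg: int = 18
    unaligned_rate: float = 0.13
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "admix_q": self.admix_q,
            "private_rate": self.private_rate,
            "missing_rate": self.missing_rate,
            "genotype_error": self.genotype_error,
            "unaligned_rate": self.unaligned_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("fst_true", "outgroup_divergence"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(
                    f"{name} must lie strictly in (0, 1); F=0 or F=1 makes the "
                    f"Balding-Nichols Beta degenerate (got {value})"
                )
        counts = {
            "n_loci": self.n_loci,
            "n_per_pop[0]": self.n_per_pop[0],
            "n_per_pop[1]": self.n_per_pop[1],
            "n_contigs": self.n_contigs,
            "n_lg": self.n_lg,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("n_admixed", "n_outgroup", "n_duplicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_duplicates > sum(self.n_per_pop):
            raise ValueError("n_duplicates exceeds the number of source-population samples")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    true_q: pd.DataFrame  # sample, q_west, population label
    freq: pd.DataFrame  # per locus: p_anc, p_west, p_east, p_outgroup
    ancestral_allele: pd.Series  # per locus: ancestral base or "unaligned"
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    config: SimConfig | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.true_q.to_csv(outdir / "truth_q.tsv", sep="\t", index=False)
        self.freq.assign(ancestral_allele=self.ancestral_allele.values).to_csv(
            outdir / "truth_freq.tsv", sep="\t", index=False
        )
        meta = {
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "config": asdict(self.config) if self.config else None,
        }
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    scale = (1.0 - f) / f
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def _flip_calls(rng, dosage: np.ndarray, error: float) -> np.ndarray:
    """Independently flip called genotypes to one of the other two dosages."""
    out = dosage.copy()
    called = out != MISSING
    flip = called & (rng.random(out.shape) < error)
    shift = rng.integers(1, 3, size=out.shape)
    out[flip] = (out[flip] + shift[flip]) % 3
    return out


def _make_map(rng, cfg: SimConfig) -> GeneticMap:
    lengths = rng.integers(50_000, 500_001, size=cfg.n_contigs)
    lgs = [f"LG{(i % cfg.n_lg) + 1}" for i in range(cfg.n_contigs)]
    orders = [i // cfg.n_lg + 1 for i in range(cfg.n_contigs)]
    contigs = [f"contig_{i + 1:04d}" for i in range(cfg.n_contigs)]
    return GeneticMap(
        pd.DataFrame({"lg": lgs, "contig": contigs, "order": orders, "length": lengths})
    )


def _place_loci(rng, cfg: SimConfig, gmap: GeneticMap) -> pd.DataFrame:
    contigs = list(gmap.table["contig"])
    lengths = dict(zip(gmap.table["contig"], gmap.table["length"]))
    idx = np.sort(rng.integers(0, len(contigs), size=cfg.n_loci))
    rows, used = [], set()
    for i in idx:
        contig = contigs[i]
        pos = int(rng.integers(1, lengths[contig] + 1))
        while (contig, pos) in used:  # collisions are rare at these densities
            pos = int(rng.integers(1, lengths[contig] + 1))
        used.add((contig, pos))
        rows.append((contig, pos))
    frame = pd.DataFrame(rows, columns=["contig", "pos"])
    frame = frame.sort_values(["contig", "pos"]).reset_index(drop=True)
    ref_idx = rng.integers(0, 4, size=cfg.n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_loci)) % 4
    frame["ref"] = _BASES[ref_idx]
    frame["alt"] = _BASES[alt_idx]
    return frame


def _call_from_reads(rng, g_true: np.ndarray, depth: np.ndarray):
    """Genotype-call layer: binomial read split, phred PLs, argmin call.

    Returns (dosage, pl). Cells with zero depth are missing with an
    uninformative PL triple (0, 0, 0).
    """
    freqs = np.array([READ_ERROR, 0.5, 1.0 - READ_ERROR])
    alt_reads = rng.binomial(depth, freqs[g_true])
    ref_reads = depth - alt_reads
    log_f = np.log10(freqs)
    log_1mf = np.log10(1.0 - freqs)
    # (N, L, 3) log10-likelihoods of each candidate genotype
    ll = alt_reads[..., None] * log_f + ref_reads[..., None] * log_1mf
    pl = np.rint(-10.0 * (ll - ll.max(axis=2, keepdims=True))).astype(np.int32)
    dosage = pl.argmin(axis=2).astype(np.int8)
    no_reads = depth == 0
    dosage[no_reads] = MISSING
    pl[no_reads] = 0
    return dosage, pl


def simulate_dataset(cfg: SimConfig):
    """Generate a synthetic survey dataset.

    Returns
    -------
    (GenotypeMatrix, SampleSheet, GeneticMap, ancestral table, SimTruth)
        The ancestral table is a DataFrame with columns
        ``contig, pos, allele`` where allele is a base or ``"unaligned"``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gmap = _make_map(rng, cfg)
    loci = _place_loci(rng, cfg, gmap)
    n_loci = cfg.n_loci

    # --- population allele frequencies (Balding-Nichols) ---
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    p_west = _balding_nichols(rng, p_anc, cfg.fst_true)
    p_east = _balding_nichols(rng, p_anc, cfg.fst_true)
    p_out = _balding_nichols(rng, p_anc, cfg.outgroup_divergence)

    n_private = int(round(cfg.private_rate * n_loci))
    if n_private:
        priv_idx = rng.choice(n_loci, size=n_private, replace=False)
        west_side = rng.random(n_private) < 0.5
        p_west[priv_idx] = np.where(west_side, 1.0, 0.0)
        p_east[priv_idx] = np.where(west_side, 0.0, 1.0)

    # --- sample roster ---
    n_w, n_e = cfg.n_per_pop
    names, regions, species, q_true = [], [], [], []
    for i in range(n_w):
        names.append(f"W{i + 1:03d}"); regions.append("North_Africa")
        species.append("P_dactylifera"); q_true.append(1.0)
    for i in range(n_e):
        names.append(f"E{i + 1:03d}"); regions.append("Arabian_Gulf")
        species.append("P_dactylifera"); q_true.append(0.0)
    for i in range(cfg.n_admixed):
        names.append(f"M{i + 1:03d}"); regions.append("Central")
        species.append("P_dactylifera"); q_true.append(cfg.admix_q)
    for i in range(cfg.n_outgroup):
        sp = "P_hanceana" if i < (cfg.n_outgroup + 1) // 2 else "P_sylvestris"
        names.append(f"O{i + 1:03d}"); regions.append("Outgroup")
        species.append(sp); q_true.append(float("nan"))

    n_samples = len(names)
    g_true = np.empty((n_samples, n_loci), dtype=np.int64)
    row = 0
    for _ in range(n_w):
        g_true[row] = rng.binomial(2, p_west); row += 1
    for _ in range(n_e):
        g_true[row] = rng.binomial(2, p_east); row += 1
    for _ in range(cfg.n_admixed):
        src_west = rng.random(n_loci) < cfg.admix_q  # per-locus source population
        g_true[row] = rng.binomial(2, np.where(src_west, p_west, p_east)); row += 1
    for _ in range(cfg.n_outgroup):
        g_true[row] = rng.binomial(2, p_out); row += 1

    # --- read depth, PLs, genotype calls, missingness ---
    depth = rng.poisson(cfg.mean_depth, size=(n_samples, n_loci)).astype(np.int32)
    dosage, pl = _call_from_reads(rng, g_true, depth)
    dropout = rng.random((n_samples, n_loci)) < cfg.missing_rate
    dosage[dropout] = MISSING
    depth[dropout] = 0
    pl[dropout] = 0

    # --- duplicate samples: two independently perturbed copies of a source call ---
    dup_pairs: list[tuple[str, str]] = []
    dup_rows, dup_names = [], []
    dup_rng = np.random.default_rng(rng.integers(2**31))
    for i in range(cfg.n_duplicates):
        base = dosage[i].copy()
        dosage[i] = _flip_calls(dup_rng, base[None, :], cfg.genotype_error)[0]
        dup_rows.append(_flip_calls(dup_rng, base[None, :], cfg.genotype_error)[0])
        dup_names.append(f"{names[i]}_dup")
        dup_pairs.append((names[i], dup_names[-1]))
    if dup_rows:
        originals = slice(0, cfg.n_duplicates)
        dosage = np.vstack([dosage, np.array(dup_rows, dtype=np.int8)])
        depth = np.vstack([depth, depth[originals]])
        pl = np.vstack([pl, pl[originals]])
        for i, nm in enumerate(dup_names):
            names.append(nm)
            regions.append(regions[i])
            species.append(species[i])
            q_true.append(q_true[i])

    # --- ancestral-allele table ---
    anc_is_alt = rng.random(n_loci) < p_out
    unaligned = rng.random(n_loci) < cfg.unaligned_rate
    anc_allele = np.where(anc_is_alt, loci["alt"], loci["ref"]).astype(object)
    anc_allele[unaligned] = UNALIGNED
    ancestral = loci[["contig", "pos"]].assign(allele=anc_allele)

    gm = GenotypeMatrix(names, loci, dosage, depth, pl)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": names,
                "region": regions,
                "species": species,
                "duplicate_of": [
                    {b: a for a, b in dup_pairs}.get(nm, "") for nm in names
                ],
            }
        )
    )
    truth = SimTruth(
        true_q=pd.DataFrame({"sample": names, "q_west": q_true}).assign(
            population=regions
        ),
        freq=pd.DataFrame(
            {"contig": loci["contig"], "pos": loci["pos"], "p_anc": p_anc,
             "p_west": p_west, "p_east": p_east, "p_outgroup": p_out}
        ),
        ancestral_allele=pd.Series(anc_allele, name="ancestral_allele"),
        duplicate_pairs=dup_pairs,
        config=cfg,
    )
    return gm, sheet, gmap, ancestral, truth


def write_dataset(outdir, gm, sheet, gmap, ancestral, truth) -> None:
    """Serialise a simulated dataset to a directory of plain-text files."""
    from .vcfio import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, outdir / "genotypes.vcf")
    sheet.to_tsv(outdir / "samples.tsv")
    gmap.to_tsv(outdir / "map.tsv")
    ancestral.to_csv(outdir / "ancestral.tsv", sep="\t", index=False)
    truth.write(outdir / "truth")


def read_ancestral_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int, "allele": str})
    for col in ("contig", "pos", "allele"):
        if col not in tab.columns:
            raise ValueError(f"ancestral table missing column {col!r}")
    return tab
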