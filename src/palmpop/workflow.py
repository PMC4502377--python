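"""End-to-end survey pipeline: simulate/load -> filter -> structure ->
assign -> differentiate -> polarize -> export, driven by one config.

Every stage writes its tables under the output directory; a machine-readable
``summary.json`` collects the headline quantities and ``summary.txt``
renders them with the survey's formatting conventions. All randomness
derives from the single configured seed, so identical configurations give
byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import (
    MIXED,
    align_runs,
    assign_populations,
    evanno_delta_k,
    run_replicates,
)
from .alignment import export_alignment, pairwise_distances
from .differentiation import (
    differentiation_table,
    exclude_lg,
    lg_enrichment,
    private_allele_summary,
    weir_cockerham_fst,
    window_density,
)
from .filters import apply_standard_filters, duplicate_concordance
from .genmap import GeneticMap
from .matrix import SampleSheet
from .ordination import GenotypePCA
from .polarization import classify_polarization, region_segregating
from .report import format_count, format_count_percent
from .simulate import SimConfig, read_ancestral_table, simulate_dataset, write_dataset
from .vcfio import read_vcf, write_vcf

logger = logging.getLogger("palmpop")


@dataclass
class PipelineConfig:
    """Survey configuration; defaults are the analysis' standard settings."""

    # inputs: either a simulation block or paths to real files
    simulate: SimConfig | None = None
    vcf: str | None = None
    samples: str | None = None
    genetic_map: str | None = None
    ancestral: str | None = None

    # filtering
    pl_min: int = 35
    min_depth: int = 10
    min_fraction: float = 0.8
    min_alt: int = 4
    max_missing: int = 15

    # structure
    k_min: int = 2
    k_max: int = 7
    replicates: int = 4
    burn_in: int = 5000
    n_reps: int = 25000

    # downstream
    purity: float = 0.75
    alpha: float = 0.01
    window_bp: int = 1_000_000
    combine_mixed_with_west: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and self.vcf is None:
            raise ValueError("config needs either a 'simulate' block or a 'vcf' path")
        if not 0.5 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0.5, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("bad K range")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, (tuple, list)):
                return [conv(x) for x in o]
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            return o

        return conv(asdict(self))


def _orient_groups(assignment, sheet: SampleSheet) -> tuple[str, str]:
    """Decide which inferred population is 'West' using claimed regions."""
    merged = assignment.merge(sheet.table, on="sample", how="left")
    pops = [c for c in assignment.columns if c.startswith("pop_")]
    west_claim = merged["region"] == "North_Africa"
    scores = {p: merged.loc[west_claim, p].sum() for p in pops}
    west = max(scores, key=scores.get) if pops else "pop_1"
    east = next((p for p in pops if p != west), "pop_2")
    return west, east


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the summary dict (also written to disk)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"versions": {"palmpop": __version__}, "seed": cfg.seed}
    timings: dict = {}
    stage_start = time.perf_counter()

    def tick(stage):
        nonlocal stage_start
        timings[stage] = round(time.perf_counter() - stage_start, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
        stage_start = time.perf_counter()

    try:
        # ---- inputs ----
        if cfg.simulate is not None:
            cfg.simulate.seed = cfg.seed
            gm, sheet, gmap, ancestral, truth = simulate_dataset(cfg.simulate)
            write_dataset(outdir / "input", gm, sheet, gmap, ancestral, truth)
        else:
            gm = read_vcf(cfg.vcf)
            sheet = SampleSheet.from_tsv(cfg.samples)
            gmap = GeneticMap.from_tsv(cfg.genetic_map) if cfg.genetic_map else None
            ancestral = read_ancestral_table(cfg.ancestral) if cfg.ancestral else None
        summary["n_samples_input"] = gm.n_samples
        summary["n_loci_input"] = gm.n_loci
        tick("input")

        # ---- filtering ----
        gm_f, report = apply_standard_filters(
            gm,
            pl_min=cfg.pl_min,
            min_depth=cfg.min_depth,
            min_fraction=cfg.min_fraction,
            min_alt_obs=cfg.min_alt,
            max_missing=cfg.max_missing,
        )
        write_vcf(gm_f, outdir / "filtered.vcf")
        report.to_tsv(outdir / "filter_report.tsv")
        summary["n_loci_filtered"] = gm_f.n_loci
        summary["filter_stages"] = report.stages
        tick("filter")

        # ---- duplicate concordance ----
        pairs = sheet.duplicate_pairs()
        if pairs:
            conc = duplicate_concordance(gm_f, pairs)
            conc.to_csv(outdir / "duplicate_concordance.tsv", sep="\t", index=False)
            mean_acc = float(conc["predicted_accuracy"].mean())
            summary["duplicates"] = {
                "n_pairs": len(pairs),
                "mean_concordance": float(conc["concordance"].mean()),
                "mean_predicted_accuracy": mean_acc,
            }
        # analyses below use each cultivar once
        dup_names = {b for _, b in pairs}
        keep = [s for s in gm_f.samples if s not in dup_names]
        gm_a = gm_f.take_samples(keep)
        sheet_a = SampleSheet(
            sheet.table[sheet.table["sample"].isin(keep)].reset_index(drop=True)
        )
        ingroup = [s for s in sheet_a.ingroup_samples() if s in keep]
        gm_in = gm_a.take_samples(ingroup)
        tick("duplicates")

        # ---- population structure ----
        ks = list(range(cfg.k_min, cfg.k_max + 1))
        runs = run_replicates(
            gm_in, ks, cfg.replicates, cfg.burn_in, cfg.n_reps, seed=cfg.seed
        )
        if len(ks) >= 3 and cfg.replicates >= 2:
            evanno = evanno_delta_k(runs)
            evanno.table.to_csv(outdir / "evanno.tsv", sep="\t", index=False)
            best_k = evanno.best_k
            summary["evanno"] = {
                "best_k": best_k,
                "delta_k": {
                    int(r.K): (None if not np.isfinite(r.delta_K) else float(r.delta_K))
                    for r in evanno.table.itertuples()
                    if not np.isnan(r.delta_K)
                },
            }
        else:
            best_k = ks[0]
        alignment = align_runs(runs[best_k])
        assignment = assign_populations(
            alignment.consensus_q, threshold=cfg.purity, samples=ingroup
        )
        assignment.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        summary["structure"] = {
            "best_k": int(best_k),
            "h_prime": float(alignment.h_prime),
            "n_mixed": int((assignment["label"] == MIXED).sum()),
            "n_per_population": {
                str(lab): int(n)
                for lab, n in assignment["label"].value_counts().sort_index().items()
            },
        }
        tick("structure")

        # ---- PCA ----
        pca = GenotypePCA(n_components=min(10, gm_a.n_samples - 1)).fit(gm_a)
        pd.DataFrame(
            pca.scores_,
            index=pd.Index(gm_a.samples, name="sample"),
            columns=[f"PC{i + 1}" for i in range(pca.scores_.shape[1])],
        ).to_csv(outdir / "pca_scores.tsv", sep="\t")
        summary["pca_variance_fraction"] = [
            round(float(v), 6) for v in pca.variance_fraction_[:5]
        ]
        tick("pca")

        # ---- differentiation ----
        west_pop, east_pop = _orient_groups(assignment, sheet_a)
        west_members = [west_pop, MIXED] if cfg.combine_mixed_with_west else [west_pop]
        grouping = {"West": west_members, "East": [east_pop]}
        labels = assignment.set_index("sample").loc[ingroup, "label"]
        table, counts = differentiation_table(
            gm_in, labels, grouping=grouping, alpha=cfg.alpha
        )
        table.to_csv(outdir / "differentiation.tsv", sep="\t", index=False)
        priv = private_allele_summary(table, counts.groups)
        fst_wm_e = weir_cockerham_fst(gm_in, labels, grouping=grouping)
        summary["private_alleles"] = priv
        summary["fst"] = {
            "west_mixed_vs_east": {
                "mean": round(fst_wm_e.mean_fst, 6),
                "weighted": round(fst_wm_e.weighted_fst, 6),
            }
        }
        strict = {"West": [west_pop], "East": [east_pop]}
        if (labels == west_pop).any():
            fst_w_e = weir_cockerham_fst(gm_in, labels, grouping=strict)
            summary["fst"]["west_vs_east"] = {
                "mean": round(fst_w_e.mean_fst, 6),
                "weighted": round(fst_w_e.weighted_fst, 6),
            }
        summary["fisher"] = {
            "n_tested": int(table["tested"].sum()),
            "n_significant": int(table["significant"].sum()),
        }
        summary["n_fixed_differences"] = int(table["fixed"].sum())
        if gmap is not None:
            enr = lg_enrichment(table, gmap, flag="significant")
            enr.to_csv(outdir / "lg_enrichment.tsv", sep="\t", index=False)
            dens = window_density(table, gmap, cfg.window_bp)
            dens.to_csv(outdir / "window_density.tsv", sep="\t", index=False)
            summary["lg_enrichment"] = {
                str(r.lg): round(float(r.fold), 4)
                for r in enr.itertuples()
                if r.n_snps > 0
            }
        tick("differentiation")

        # ---- polarization ----
        if ancestral is not None:
            seg = region_segregating(
                gm_in, labels, west_group=west_members, east_group=[east_pop]
            )
            pol = classify_polarization(seg, ancestral)
            pol.records.to_csv(outdir / "polarization.tsv", sep="\t", index=False)
            pol.per_scaffold.to_csv(
                outdir / "polarization_by_scaffold.tsv", sep="\t", index=False
            )
            n_seg = len(pol.records)
            summary["polarization"] = {
                "n_segregating": n_seg,
                **{
                    f"n_{cls}": int((pol.records["class"] == cls).sum())
                    for cls in ("east_deviated", "west_deviated", "both_deviated", "unaligned")
                },
            }
        tick("polarization")

        # ---- alignment export ----
        aln = export_alignment(gm_a, mode="homozygous")
        aln.write_fasta(outdir / "alignment.fasta")
        aln.write_phylip(outdir / "alignment.phy")
        dist, _ = pairwise_distances(aln)
        pd.DataFrame(dist, index=aln.names, columns=aln.names).to_csv(
            outdir / "pairwise_distances.tsv", sep="\t"
        )
        tick("alignment")
    except Exception:
        logger.exception("pipeline aborted; partial outputs retained in %s", outdir)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary["timings_s"] = timings
    (outdir / "summary.json").write_text(_stable_json(summary))
    (outdir / "summary.txt").write_text(summarize(summary))
    return summary


def _stable_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    # timings vary run to run; byte-identical summaries need them out of the
    # canonical payload
    payload = {k: v for k, v in obj.items() if k != "timings_s"}
    return json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n"


def summarize(summary: dict) -> str:
    """Render the headline numbers with the survey's formatting conventions."""
    lines = [f"palmpop {summary['versions']['palmpop']} summary (seed {summary['seed']})"]
    n_loci = summary.get("n_loci_filtered", 0)
    lines.append(
        f"Loci: {format_count(summary.get('n_loci_input', 0))} input, "
        f"{format_count(n_loci)} after filtering"
    )
    if "duplicates" in summary:
        acc = summary["duplicates"]["mean_predicted_accuracy"]
        lines.append(f"Duplicate pairs: predicted genotyping accuracy {100 * acc:.1f}%")
    if "structure" in summary:
        st = summary["structure"]
        lines.append(
            f"Structure: best K = {st['best_k']}, H' = {st['h_prime']:.2f}, "
            f"{st['n_mixed']} samples mixed"
        )
    if "fst" in summary:
        for key, vals in summary["fst"].items():
            lines.append(
                f"Fst ({key}): mean {vals['mean']:.3f}, weighted {vals['weighted']:.3f}"
            )
    if "private_alleles" in summary:
        pa = summary["private_alleles"]
        lines.append(
            "Nonreference private alleles: "
            + format_count_percent(pa["nonref_private_total"], pa["n_positions"])
        )
        for group, n in pa["nonref_private_by_group"].items():
            lines.append(f"  from {group}: {format_count(n)}")
    if "fisher" in summary:
        fi = summary["fisher"]
        lines.append(
            "Significantly segregating SNPs: "
            + format_count_percent(fi["n_significant"], max(fi["n_tested"], 1))
        )
    if "n_fixed_differences" in summary:
        lines.append(f"Fixed differences: {format_count(summary['n_fixed_differences'])}")
    if "polarization" in summary:
        po = summary["polarization"]
        n = po["n_segregating"]
        if n:
            lines.append(
                f"Region-segregating SNPs: {format_count(n)}; "
                f"East deviated {format_count_percent(po['n_east_deviated'], n)}, "
                f"West deviated {format_count_percent(po['n_west_deviated'], n)}, "
                f"both {format_count_percent(po['n_both_deviated'], n)}, "
                f"unaligned {format_count_percent(po['n_unaligned'], n)}"
            )
    return "\n".join(lines) + "\n"
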