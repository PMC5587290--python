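"""End-to-end orchestration: simulate -> detect -> annotate -> enrich ->
intersect -> size stats, seeded throughout, with a run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .annotation import (
    annotate_clusters,
    feature_position_profile,
    gc_content_vs_flanks,
    load_bed,
    per_sample_mean,
    tabulate_by_group,
    tss_distance_profile,
)
from .enrichment import enrichment_table
from .intersects import (
    expected_gene_partition,
    gene_sets,
    group_intersect_summary,
    shared_gene_partition,
)
from .intervals import IntervalIndex
from .junctions import ClusterParams, ClusterStats, call_clusters_from_file, write_clusters_bed
from .samples import CONDITIONS, DRUGS, default_sample_sheet, read_sample_sheet, write_sample_sheet
from .size_stats import compare_length_groups, estimate_periodicity, size_summary, treatment_fractions
from .synthetic import (
    AnnotationBundle,
    CircleModel,
    NoiseParams,
    ToyGenomeSpec,
    emit_chimeric_junctions,
    generate_toy_genome,
    simulate_circles,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "microdna_out"
    seed: int = 0
    simulate: bool = True
    # simulate mode
    n_replicates: int = 2
    genome_spec: dict = field(default_factory=dict)
    circle_model: dict = field(default_factory=dict)
    jitter: int = 0
    background: float = 0.05
    # file mode
    junction_files: dict = field(default_factory=dict)  # sample_id -> path
    tracks_dir: str | None = None
    genome_fasta: str | None = None
    sample_sheet: str | None = None
    # analysis parameters
    extension: int = 10
    min_support: int = 1
    size_min: int = 20
    size_max: int = 2000
    shuffles: int = 1000
    flank_distance: int = 5000
    gc_flank: int = 1000
    profile_window: int = 5000
    partition_shuffles: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(self.extension, self.min_support,
                             self.size_min, self.size_max)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Pre-flight checks; returns a list of messages (empty = pass).

    Messages prefixed ERROR abort the run; WARNING messages do not.
    """
    msgs: list[str] = []
    if config.simulate:
        if config.n_replicates < 1:
            msgs.append("ERROR: n_replicates must be >= 1")
        return msgs
    if not config.junction_files:
        msgs.append("ERROR: no junction files configured")
    for sid, path in config.junction_files.items():
        p = Path(path)
        if not p.exists():
            msgs.append(f"ERROR: junction file missing for {sid}: {path}")
            continue
        with open(p) as fh:
            first = fh.readline().rstrip("\n")
        if first and len(first.split("\t")) < 14:
            msgs.append(
                f"ERROR: {path}: {len(first.split(chr(9)))} columns "
                "(need 14 STAR chimeric-junction columns)"
            )
    for label, path in (("tracks_dir", config.tracks_dir),
                        ("genome_fasta", config.genome_fasta),
                        ("sample_sheet", config.sample_sheet)):
        if path is None:
            msgs.append(f"ERROR: {label} is required when simulate=false")
        elif not Path(path).exists():
            msgs.append(f"ERROR: {label} not found: {path}")
    if config.sample_sheet and Path(config.sample_sheet).exists():
        samples = read_sample_sheet(config.sample_sheet)
        if not samples:
            msgs.append("ERROR: sample sheet is empty")
        present = {(s.drug, s.condition) for s in samples}
        for drug in sorted({s.drug for s in samples}):
            for cond in CONDITIONS:
                if (drug, cond) not in present:
                    msgs.append(
                        f"WARNING: sample sheet has no {cond} sample for "
                        f"{drug}; that group is skipped"
                    )
        missing = {s.sample_id for s in samples} - set(config.junction_files)
        if missing:
            msgs.append(
                f"WARNING: no junction file for samples {sorted(missing)}"
            )
    return msgs


def load_bundle(tracks_dir: str | Path, chrom_sizes: dict[str, int]) -> AnnotationBundle:
    """Rebuild an annotation bundle from the track files the generator
    writes (BED6 / narrowPeak)."""
    d = Path(tracks_dir)

    def idx(name: str) -> IntervalIndex:
        p = d / name
        return IntervalIndex(load_bed(p) if p.exists() else [])

    tss = load_bed(d / "tss.bed") if (d / "tss.bed").exists() else []
    exp_p = d / "expressed_tss.bed"
    expressed = load_bed(exp_p) if exp_p.exists() else tss
    repeats: dict[str, IntervalIndex] = {}
    rep_p = d / "repeats.bed"
    if rep_p.exists():
        by_class: dict[str, list] = {}
        for iv in load_bed(rep_p):
            by_class.setdefault(iv.name or "repeat", []).append(iv)
        repeats = {k: IntervalIndex(v) for k, v in by_class.items()}
    histone = {
        mark: idx(f"{mark}.narrowPeak")
        for mark in ("H3K9ac", "H3K27me3", "H3K9me3")
    }
    return AnnotationBundle(
        chrom_sizes=chrom_sizes,
        genes=idx("genes.bed"),
        exons=idx("exons.bed"),
        introns=idx("introns.bed"),
        utr5=idx("utr5.bed"),
        utr3=idx("utr3.bed"),
        promoters=idx("promoters.bed"),
        tss=tss,
        expressed_tss=expressed,
        open_chromatin=idx("open_chromatin.bed"),
        histone=histone,
        repeats=repeats,
    )


def _category_indexes(bundle: AnnotationBundle) -> dict[str, IntervalIndex]:
    cats = {
        "genic": bundle.genes, "exonic": bundle.exons,
        "intronic": bundle.introns, "utr5": bundle.utr5,
        "utr3": bundle.utr3, "promoter": bundle.promoters,
        "active": bundle.open_chromatin,
    }
    return {k: v for k, v in cats.items()}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the consolidated report directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    msgs = validate_inputs(config)
    errors = [m for m in msgs if m.startswith("ERROR")]
    for m in msgs:
        logger.warning(m)
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    # --- inputs: simulate or load -------------------------------------
    if config.simulate:
        spec = ToyGenomeSpec(**{**config.genome_spec, "seed": config.seed})
        genome, bundle = generate_toy_genome(spec, outdir / "tracks")
        samples = default_sample_sheet(config.n_replicates)
        write_sample_sheet(samples, outdir / "samples.tsv")
        model = CircleModel(**{**config.circle_model, "seed": config.seed + 1})
        circles = simulate_circles(bundle, model, samples)
        emit = emit_chimeric_junctions(
            circles, outdir / "junctions", bundle.chrom_sizes, samples=samples,
            noise=NoiseParams(config.jitter, config.background),
            seed=config.seed + 2,
        )
        junction_files = {s.sample_id: emit.junction_paths[s.sample_id]
                          for s in samples}
        manifest["stages"]["simulate"] = {
            "n_circles": len(circles),
            "n_true_junction_lines": sum(emit.n_true_lines.values()),
            "n_background_lines": sum(emit.n_background.values()),
        }
    else:
        samples = read_sample_sheet(config.sample_sheet)
        fa = Fasta(config.genome_fasta)
        genome = {name: str(fa[name][:]) for name in fa.keys()}
        chrom_sizes = {name: len(seq) for name, seq in genome.items()}
        bundle = load_bundle(config.tracks_dir, chrom_sizes)
        junction_files = {
            sid: Path(p) for sid, p in config.junction_files.items()
        }
        samples = [s for s in samples if s.sample_id in junction_files]

    # --- detect -------------------------------------------------------
    params = config.cluster_params()
    stats = ClusterStats()
    clusters_by_sample = {}
    bed_dir = outdir / "clusters"
    bed_dir.mkdir(exist_ok=True)
    for s in samples:
        cl = call_clusters_from_file(
            junction_files[s.sample_id], params, sample_id=s.sample_id,
            stats=stats,
        )
        clusters_by_sample[s.sample_id] = cl
        write_clusters_bed(cl, bed_dir / f"{s.sample_id}.clusters.bed")
    all_clusters = [c for cl in clusters_by_sample.values() for c in cl]
    manifest["stages"]["detect"] = {
        "n_junctions": stats.n_junctions,
        "n_circular": stats.n_circular,
        "n_clusters_raw": stats.n_clusters_raw,
        "n_dropped_support": stats.n_dropped_support,
        "n_dropped_size": stats.n_dropped_size,
        "n_clusters": stats.n_clusters,
    }

    # --- annotate -----------------------------------------------------
    annotations = annotate_clusters(all_clusters, bundle)
    table1 = tabulate_by_group(annotations, samples)
    table1.to_csv(outdir / "group_counts.tsv", sep="\t")
    manifest["stages"]["annotate"] = {
        "n_annotated": len(annotations),
        "per_sample_mean": per_sample_mean(table1, max(len(samples), 1)),
    }
    if bundle.expressed_tss:
        prof = tss_distance_profile(all_clusters, bundle.expressed_tss,
                                    config.profile_window)
        prof.to_csv(outdir / "tss_profile.tsv", sep="\t", index=False)
    for mark, idx in bundle.histone.items():
        prof = feature_position_profile(all_clusters, list(idx),
                                        config.profile_window)
        prof.to_csv(outdir / f"profile_{mark}.tsv", sep="\t", index=False)
    for cls, idx in bundle.repeats.items():
        prof = feature_position_profile(all_clusters, list(idx),
                                        config.profile_window)
        prof.to_csv(outdir / f"profile_repeat_{cls}.tsv", sep="\t", index=False)
    gc_df, gc_p = gc_content_vs_flanks(all_clusters, genome, config.gc_flank)
    gc_df.to_csv(outdir / "gc_vs_flanks.tsv", sep="\t", index=False)
    manifest["stages"]["gc"] = {
        "n": len(gc_df),
        "mean_gc_cluster": float(gc_df["gc_cluster"].mean()) if len(gc_df) else None,
        "mean_gc_flank": float(gc_df["gc_flank"].mean()) if len(gc_df) else None,
        "mannwhitney_p": gc_p,
    }

    # --- enrichment ---------------------------------------------------
    meta = {s.sample_id: s for s in samples}
    cats = _category_indexes(bundle)
    enr_rows = []
    for drug in DRUGS:
        for cond in CONDITIONS:
            group_clusters = [
                c for c in all_clusters
                if meta[c.sample_id].group == (drug, cond)
            ]
            if not group_clusters:
                continue
            results = enrichment_table(
                group_clusters, bundle.chrom_sizes, cats,
                n=config.shuffles, seed=config.seed + 10,
            )
            for r in results:
                enr_rows.append(
                    {"drug": drug, "condition": cond, "category": r.category,
                     "observed": r.observed, "expected": r.expected,
                     "fold": r.fold, "p_value": r.p_value}
                )
    pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                  index=False)
    manifest["stages"]["enrichment"] = {"n_rows": len(enr_rows)}

    # --- intersects ---------------------------------------------------
    int_rows = []
    group_gene_sets: dict[str, dict[str, set[str]]] = {d: {} for d in DRUGS}
    group_clusters_map: dict[str, dict[str, list]] = {d: {} for d in DRUGS}
    for drug in DRUGS:
        for cond in CONDITIONS:
            sub = {
                s.sample_id: clusters_by_sample[s.sample_id]
                for s in samples if s.group == (drug, cond)
            }
            if not sub:
                continue
            summary = group_intersect_summary(sub, bundle.genes, (drug, cond))
            int_rows.append(
                {"drug": drug, "condition": cond,
                 "gene_n": summary.gene.n, "gene_total": summary.gene.total,
                 "gene_percent": summary.gene.percent,
                 "cluster_n": summary.cluster.n,
                 "cluster_total": summary.cluster.total,
                 "cluster_percent": summary.cluster.percent}
            )
            flat = [c for cl in sub.values() for c in cl]
            group_clusters_map[drug][cond] = flat
            group_gene_sets[drug][cond] = set().union(
                *gene_sets(flat, bundle.genes), set()
            )
    pd.DataFrame(int_rows).to_csv(outdir / "intersects.tsv", sep="\t",
                                  index=False)
    part_rows = []
    for drug in DRUGS:
        if not group_gene_sets[drug]:
            continue
        observed = shared_gene_partition(group_gene_sets[drug])
        expected, stat, p = expected_gene_partition(
            group_clusters_map[drug], bundle.genes, bundle.chrom_sizes,
            n=config.partition_shuffles, seed=config.seed + 20,
        )
        for cell, obs in sorted(observed.items(), key=lambda kv: sorted(kv[0])):
            part_rows.append(
                {"drug": drug, "groups": "+".join(sorted(cell)),
                 "observed": obs, "expected": expected[cell],
                 "chi2": stat, "p_value": p}
            )
    pd.DataFrame(part_rows).to_csv(outdir / "gene_partition.tsv", sep="\t",
                                   index=False)
    manifest["stages"]["intersects"] = {"n_groups": len(int_rows)}

    # --- size stats ---------------------------------------------------
    lengths_all = np.array([c.interval.length for c in all_clusters])
    size_rows = []
    lengths_by_cond: dict[str, dict[str, np.ndarray]] = {d: {} for d in DRUGS}
    if len(lengths_all):
        summ = size_summary(lengths_all)
        size_rows.append(
            {"group": "all", "n": summ.n, "mean": summ.mean,
             "p2.5": summ.central95[0], "p97.5": summ.central95[1],
             "q25": summ.iqr[0], "q75": summ.iqr[1]}
        )
        summ.histogram.to_csv(outdir / "size_histogram.tsv", sep="\t",
                              index=False)
    for drug in DRUGS:
        for cond in CONDITIONS:
            lens = np.array([
                c.interval.length for c in all_clusters
                if meta[c.sample_id].group == (drug, cond)
            ])
            if len(lens) == 0:
                continue
            lengths_by_cond[drug][cond] = lens
            summ = size_summary(lens)
            size_rows.append(
                {"group": f"{drug}_{cond}", "n": summ.n, "mean": summ.mean,
                 "p2.5": summ.central95[0], "p97.5": summ.central95[1],
                 "q25": summ.iqr[0], "q75": summ.iqr[1]}
            )
    pd.DataFrame(size_rows).to_csv(outdir / "size_summary.tsv", sep="\t",
                                   index=False)
    per = estimate_periodicity(lengths_all, seed=config.seed + 30) \
        if len(lengths_all) else None
    with open(outdir / "periodicity.tsv", "w") as fh:
        fh.write("period_bp\tprominence\tsignificant\n")
        if per is not None:
            fh.write(f"{per.period}\t{per.prominence:.4f}\t{per.significant}\n")
    contrast_rows = []
    frac_rows = []
    for drug in DRUGS:
        for (g1, g2), p in compare_length_groups(lengths_by_cond[drug]).items():
            contrast_rows.append(
                {"drug": drug, "contrast": f"{g1}_vs_{g2}", "p_value": p}
            )
        try:
            frac_rows.append(treatment_fractions(table1, drug))
        except ValueError:
            logger.info("treatment fractions skipped for %s (empty groups)",
                        drug)
    pd.DataFrame(contrast_rows).to_csv(outdir / "length_contrasts.tsv",
                                       sep="\t", index=False)
    if frac_rows:
        pd.concat(frac_rows).to_csv(outdir / "treatment_fractions.tsv",
                                    sep="\t", index=False)
    manifest["stages"]["size_stats"] = {
        "n_lengths": int(len(lengths_all)),
        "period_bp": per.period if per else None,
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return outdir
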