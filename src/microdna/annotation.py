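"""Genomic annotation of microDNA clusters.

Feature flags (genic/exonic/intronic/UTR/promoter/open-chromatin) use a
minimum overlap of 1 bp and are non-exclusive: a cluster spanning an
exon-intron boundary is both exonic and intronic. "NA" marks clusters that
touch neither a gene feature nor a promoter (e.g. intergenic loci);
"Active"/"Inactive" partition clusters by open-chromatin overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval
from .junctions import MicroDNACluster
from .samples import CONDITIONS, DRUGS, SampleMeta
from .synthetic import AnnotationBundle

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "Genic", "Exonic", "Intronic", "5UTR", "3UTR", "Promoter",
    "NA", "Active", "Inactive", "Total",
]


@dataclass
class ClusterAnnotation:
    cluster: MicroDNACluster
    genic: bool
    exonic: bool
    intronic: bool
    utr5: bool
    utr3: bool
    promoter: bool
    active: bool

    @property
    def na(self) -> bool:
        """No investigated gene feature: neither genic nor promoter."""
        return not (self.genic or self.promoter)


def annotate_clusters(
    clusters: Sequence[MicroDNACluster], bundle: AnnotationBundle
) -> list[ClusterAnnotation]:
    """Flag each cluster for >= 1 bp overlap with every annotation track."""
    out = []
    n_missing = 0
    known = set(bundle.chrom_sizes)
    for c in clusters:
        iv = c.interval
        if iv.chrom not in known:
            n_missing += 1
            out.append(ClusterAnnotation(c, *([False] * 7)))
            continue
        out.append(
            ClusterAnnotation(
                c,
                genic=bundle.genes.overlaps_any(iv.chrom, iv.start, iv.end),
                exonic=bundle.exons.overlaps_any(iv.chrom, iv.start, iv.end),
                intronic=bundle.introns.overlaps_any(iv.chrom, iv.start, iv.end),
                utr5=bundle.utr5.overlaps_any(iv.chrom, iv.start, iv.end),
                utr3=bundle.utr3.overlaps_any(iv.chrom, iv.start, iv.end),
                promoter=bundle.promoters.overlaps_any(iv.chrom, iv.start, iv.end),
                active=bundle.open_chromatin.overlaps_any(iv.chrom, iv.start, iv.end),
            )
        )
    if n_missing:
        logger.warning(
            "%d clusters on chromosomes absent from the annotation bundle "
            "(flagged NA/inactive)", n_missing,
        )
    return out


def tabulate_by_group(
    annotations: Sequence[ClusterAnnotation],
    sample_sheet: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Count unique clusters per (drug, condition) group and feature flag.

    Unique cluster identity is (sample, chrom, start, end): the same locus
    seen in two samples of a group counts twice, so group Totals are sums
    over the group's samples. Rows cover all 8 drug x condition groups.
    """
    meta = {s.sample_id: s for s in sample_sheet}
    index = pd.MultiIndex.from_tuples(
        [(d, c) for d in DRUGS for c in CONDITIONS], names=["drug", "condition"]
    )
    table = pd.DataFrame(0, index=index, columns=TABLE_COLUMNS, dtype=int)
    seen: set[tuple] = set()
    for ann in annotations:
        sid = ann.cluster.sample_id
        if sid not in meta:
            raise KeyError(f"sample {sid!r} missing from the sample sheet")
        key = ann.cluster.key()
        if key in seen:
            continue
        seen.add(key)
        row = meta[sid].group
        if row not in table.index:
            raise KeyError(f"unknown group label {row}")
        table.loc[row, "Total"] += 1
        for col, flag in [
            ("Genic", ann.genic), ("Exonic", ann.exonic),
            ("Intronic", ann.intronic), ("5UTR", ann.utr5),
            ("3UTR", ann.utr3), ("Promoter", ann.promoter),
            ("NA", ann.na), ("Active", ann.active),
            ("Inactive", not ann.active),
        ]:
            if flag:
                table.loc[row, col] += 1
    return table


def per_sample_mean(table: pd.DataFrame, n_samples: int) -> float:
    """Mean number of unique clusters per sample over the whole design."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return float(table["Total"].sum()) / n_samples


def tss_distance_profile(
    clusters: Sequence[MicroDNACluster],
    expressed_tss: Sequence[GenomicInterval],
    window: int = 5000,
) -> pd.DataFrame:
    """Cluster-center density around (expressed) TSSs.

    For every TSS-centered window of +-`window` bp, each cluster whose
    center falls inside contributes one count at its strand-oriented offset
    (upstream negative). Counts are normalized by the total number of
    clusters, giving the fraction of microDNAs observed at each position.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not expressed_tss:
        raise ValueError("no TSS provided")
    counts = np.zeros(2 * window + 1)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in expressed_tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    for c in clusters:
        center = c.interval.center
        for t in by_chrom.get(c.interval.chrom, ()):
            off = center - t.start
            if t.strand == "-":
                off = -off
            if -window <= off <= window:
                counts[off + window] += 1
    total = max(len(clusters), 1)
    return pd.DataFrame(
        {"offset": np.arange(-window, window + 1), "fraction": counts / total}
    )


def feature_position_profile(
    clusters: Sequence[MicroDNACluster],
    features: Sequence[GenomicInterval],
    window: int = 5000,
) -> pd.DataFrame:
    """Mean feature coverage at each offset from cluster centers.

    The value at offset o is the average (over clusters) number of feature
    intervals covering position center + o — the expected number of peaks
    at that position near a microDNA. Offsets are genomic (no strand
    orientation). Empty feature lists give an all-zero profile.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    cov = np.zeros(2 * window + 1)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for c in clusters:
        center = c.interval.center
        lo, hi = center - window, center + window + 1
        for f in by_chrom.get(c.interval.chrom, ()):
            if f.end <= lo or f.start >= hi:
                continue
            a = max(f.start, lo) - center + window
            b = min(f.end, hi) - center + window
            cov[a:b] += 1
    n = max(len(clusters), 1)
    return pd.DataFrame(
        {"offset": np.arange(-window, window + 1), "mean_coverage": cov / n}
    )


def _gc_fraction(seq: str) -> float | None:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (seq.count("G") + seq.count("C")) / acgt


def gc_content_vs_flanks(
    clusters: Sequence[MicroDNACluster],
    genome: Mapping[str, str],
    flank: int = 1000,
) -> tuple[pd.DataFrame, float]:
    """Per-cluster GC of the circle vs its pooled 1 kb flanks.

    GC = (G+C)/(A+C+G+T); N bases drop out of the denominator. The two
    flanks are pooled into one value per cluster (clipped at chromosome
    ends). Returns the per-cluster table and the two-sided Mann-Whitney p
    comparing the cluster and flank GC vectors.
    """
    rows = []
    n_excluded = 0
    for c in clusters:
        iv = c.interval
        seq = genome[iv.chrom]
        gc_c = _gc_fraction(seq[iv.start:iv.end])
        left = seq[max(0, iv.start - flank):iv.start]
        right = seq[iv.end:iv.end + flank]
        gc_f = _gc_fraction(left + right)
        if gc_c is None or gc_f is None:
            n_excluded += 1
            continue
        rows.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "sample_id": c.sample_id, "gc_cluster": gc_c, "gc_flank": gc_f}
        )
    if n_excluded:
        logger.warning("%d clusters with undefined GC excluded", n_excluded)
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample_id",
                       "gc_cluster", "gc_flank"]
    )
    if len(df) == 0:
        return df, float("nan")
    if df["gc_cluster"].nunique() == 1 and df["gc_flank"].nunique() == 1 and \
            df["gc_cluster"].iloc[0] == df["gc_flank"].iloc[0]:
        return df, 1.0
    p = float(
        sps.mannwhitneyu(df["gc_cluster"], df["gc_flank"],
                         alternative="two-sided").pvalue
    )
    return df, p


def load_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (or narrowPeak: extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out
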