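"""Cross-sample redundancy of microDNA loci.

Two notions of sharing between the samples of a group:

* cluster intersects — clusters from different samples that fall in the
  same continual genomic segment (union of all clusters merged at >= 1 bp
  overlap);
* gene intersects — clusters from different samples hosted by the same
  gene, with no positional overlap required.

Both are counted in cluster units (n intersecting / total clusters).
Expected-by-chance levels come from length-preserving random re-placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .intervals import IntervalIndex, merge_intervals
from .junctions import MicroDNACluster


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IntersectCount:
    n: int
    total: int

    @property
    def percent(self) -> float:
        """100*n/total rounded half-up to one decimal."""
        if self.total == 0:
            return float("nan")
        return round_half_up(100.0 * self.n / self.total, 1)


@dataclass
class IntersectSummary:
    group: tuple[str, str]
    gene: IntersectCount
    cluster: IntersectCount


def cluster_intersects(
    clusters_by_sample: Mapping[str, Sequence[MicroDNACluster]],
) -> IntersectCount:
    """Clusters positionally shared between >= 2 samples of the group.

    The union of all clusters is merged into continual segments (>= 1 bp
    overlap); every cluster whose segment holds clusters from at least two
    distinct samples counts as intersecting. With a single sample the
    count is 0 by definition.
    """
    all_clusters = [
        (sid, c) for sid, cs in clusters_by_sample.items() for c in cs
    ]
    total = len(all_clusters)
    if len(clusters_by_sample) < 2 or total == 0:
        return IntersectCount(0, total)
    by_chrom: dict[str, list[tuple[str, MicroDNACluster]]] = {}
    for sid, c in all_clusters:
        by_chrom.setdefault(c.interval.chrom, []).append((sid, c))
    n = 0
    for chrom, items in by_chrom.items():
        segments = merge_intervals(
            (c.interval.start, c.interval.end) for _, c in items
        )
        seg_starts = np.array([s for s, _ in segments])
        seg_samples: list[set[str]] = [set() for _ in segments]
        seg_members: list[list[int]] = [[] for _ in segments]
        for i, (sid, c) in enumerate(items):
            si = int(np.searchsorted(seg_starts, c.interval.start, side="right")) - 1
            seg_samples[si].add(sid)
            seg_members[si].append(i)
        for samples_in_seg, members in zip(seg_samples, seg_members):
            if len(samples_in_seg) >= 2:
                n += len(members)
    return IntersectCount(n, total)


def gene_sets(
    clusters: Sequence[MicroDNACluster], gene_track: IntervalIndex
) -> list[frozenset[str]]:
    """The set of gene names each cluster overlaps by >= 1 bp."""
    return [
        frozenset(
            g.name for g in gene_track.overlapping(
                c.interval.chrom, c.interval.start, c.interval.end
            )
        )
        for c in clusters
    ]


def gene_intersects(
    clusters_by_sample: Mapping[str, Sequence[MicroDNACluster]],
    gene_track: IntervalIndex,
) -> IntersectCount:
    """Clusters sharing a host gene with a cluster from another sample.

    A cluster overlapping several genes intersects through any of them;
    positional overlap is not required.
    """
    gene_samples: dict[str, set[str]] = {}
    per_cluster: list[tuple[str, frozenset[str]]] = []
    total = 0
    for sid, cs in clusters_by_sample.items():
        for c, genes in zip(cs, gene_sets(cs, gene_track)):
            total += 1
            per_cluster.append((sid, genes))
            for g in genes:
                gene_samples.setdefault(g, set()).add(sid)
    n = sum(
        1
        for sid, genes in per_cluster
        if any(len(gene_samples[g] - {sid}) > 0 for g in genes)
    )
    return IntersectCount(n, total)


def intersect_contrast(a: IntersectCount, b: IntersectCount) -> float:
    """Two-tailed chi-square p for the difference in intersect rates."""
    table = np.array([[a.n, a.total - a.n], [b.n, b.total - b.n]])
    if table.sum() == 0 or (table.sum(axis=0) == 0).any():
        return float("nan")
    return float(sps.chi2_contingency(table, correction=False)[1])


def shared_gene_partition(
    group_genes: Mapping[str, set[str]],
) -> dict[frozenset[str], int]:
    """Venn partition of microDNA-derived gene identities across groups.

    Returns, for every nonempty combination of groups, the number of genes
    found in exactly those groups; cell counts sum to the size of the
    union of all gene sets.
    """
    names = list(group_genes)
    partition: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(group_genes[g] for g in combo)) \
                if combo else set()
            outside = set.union(
                *(group_genes[g] for g in names if g not in combo), set()
            )
            partition[frozenset(combo)] = len(inside - outside)
    return partition


def expected_gene_partition(
    clusters_by_group: Mapping[str, Sequence[MicroDNACluster]],
    gene_track: IntervalIndex,
    chrom_sizes: Mapping[str, int],
    n: int = 1000,
    seed: int = 0,
) -> tuple[dict[frozenset[str], float], float, float]:
    """Expected Venn partition under length-preserving random re-placement.

    Each iteration re-places every cluster uniformly genome-wide (length
    kept), reassigns gene sets and recomputes the partition; the expected
    cell value is the per-cell median. Returns (expected partition,
    chi-square statistic, p) comparing observed vs expected cell vectors
    (cells with expected 0 are skipped; df = cells - 1).
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    observed = shared_gene_partition(
        {
            g: set().union(*gene_sets(cs, gene_track), set())
            for g, cs in clusters_by_group.items()
        }
    )
    cells = list(observed)
    sims = np.zeros((n, len(cells)))
    group_lengths = {
        g: np.array([c.interval.length for c in cs], dtype=np.int64)
        for g, cs in clusters_by_group.items()
    }
    for it in range(n):
        iter_genes: dict[str, set[str]] = {}
        for g, lengths in group_lengths.items():
            m = len(lengths)
            genes: set[str] = set()
            if m:
                placeable = np.maximum(sizes[None, :] - lengths[:, None] + 1, 0)
                probs = placeable / placeable.sum(axis=1, keepdims=True)
                cum = np.cumsum(probs, axis=1)
                u = rng.random(m)
                chrom_idx = (u[:, None] > cum).sum(axis=1)
                offs = (rng.random(m) * placeable[np.arange(m), chrom_idx]
                        ).astype(np.int64)
                for i in range(m):
                    chrom = chroms[chrom_idx[i]]
                    s = int(offs[i])
                    genes.update(
                        gv.name for gv in gene_track.overlapping(
                            chrom, s, s + int(lengths[i])
                        )
                    )
            iter_genes[g] = genes
        part = shared_gene_partition(iter_genes)
        sims[it] = [part[c] for c in cells]
    expected = {c: float(np.median(sims[:, i])) for i, c in enumerate(cells)}
    obs_vec = np.array([observed[c] for c in cells], dtype=float)
    exp_vec = np.array([expected[c] for c in cells])
    mask = exp_vec > 0
    if mask.sum() == 0:
        return expected, 0.0, 1.0
    stat = float(np.sum((obs_vec[mask] - exp_vec[mask]) ** 2 / exp_vec[mask]))
    df = max(int(mask.sum()) - 1, 1)
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return expected, stat, p


def group_intersect_summary(
    clusters_by_sample: Mapping[str, Sequence[MicroDNACluster]],
    gene_track: IntervalIndex,
    group: tuple[str, str] = ("", ""),
) -> IntersectSummary:
    return IntersectSummary(
        group=group,
        gene=gene_intersects(clusters_by_sample, gene_track),
        cluster=cluster_intersects(clusters_by_sample),
    )
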