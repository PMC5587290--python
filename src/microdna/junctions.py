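"""Chimeric-junction parsing and microDNA cluster calling.

Two callers are provided. The junction method parses STAR-style chimeric
junction files, keeps head-to-tail same-strand intrachromosomal junctions
(the geometry a circular template produces) and groups them by recursive
10 bp extension: junctions whose breakpoint pairs chain together within the
extension distance at BOTH ends form one cluster (transitive closure, so
the result does not depend on input order). The island method instead
nominates circles from reads carrying identical leading and trailing
soft-clips, then reuses the same clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

MIN_CLIP_LENGTH = 5  # shortest soft-clip accepted as junction evidence


@dataclass(frozen=True)
class ChimericJunction:
    """One read's intrachromosomal breakpoint pair (0-based internally)."""

    read_id: str
    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_type: int = 0

    def __post_init__(self) -> None:
        if self.pos_donor < 0 or self.pos_acceptor < 0:
            raise ValueError("breakpoint positions must be >= 0")
        if self.strand_donor not in "+-" or self.strand_acceptor not in "+-":
            raise ValueError("strands must be '+' or '-'")

    @property
    def circular_consistent(self) -> bool:
        """True for head-to-tail geometry on one chromosome and strand:
        the acceptor breakpoint lies upstream of the donor breakpoint."""
        return (
            self.chrom_donor == self.chrom_acceptor
            and self.strand_donor == self.strand_acceptor
            and self.pos_acceptor < self.pos_donor
        )


@dataclass
class ClusterParams:
    extension: int = 10
    min_support: int = 1
    size_min: int = 20
    size_max: int = 2000

    def __post_init__(self) -> None:
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if not 0 < self.size_min < self.size_max:
            raise ValueError("need 0 < size_min < size_max")


@dataclass
class MicroDNACluster:
    """A candidate circle: interval spanned by its supporting junctions."""

    sample_id: str
    interval: GenomicInterval
    support: int
    read_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.interval.length

    def key(self) -> tuple[str, str, int, int]:
        return (self.sample_id, self.interval.chrom,
                self.interval.start, self.interval.end)


@dataclass
class ClusterStats:
    """Per-stage record counts for the run manifest."""

    n_junctions: int = 0
    n_circular: int = 0
    n_clusters_raw: int = 0
    n_dropped_support: int = 0
    n_dropped_size: int = 0
    n_clusters: int = 0


def parse_chimeric_junctions(
    path: str | Path, strict: bool = False
) -> list[ChimericJunction]:
    """Read a 14-column STAR-dialect chimeric junction file.

    File coordinates are 1-based and converted to the internal 0-based
    convention (the donor column holds the first base past the circle body,
    so internally pos_donor is a half-open end). Malformed lines are skipped
    and counted (raised in strict mode).
    """
    records: list[ChimericJunction] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) < 14:
                    raise ValueError(f"{len(fields)} columns (need 14)")
                rec = ChimericJunction(
                    read_id=fields[9],
                    chrom_donor=fields[0],
                    pos_donor=int(fields[1]) - 1,
                    strand_donor=fields[2],
                    chrom_acceptor=fields[3],
                    pos_acceptor=int(fields[4]) - 1,
                    strand_acceptor=fields[5],
                    junction_type=int(fields[6]),
                )
            except ValueError as exc:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                n_bad += 1
                continue
            records.append(rec)
    if n_bad:
        logger.warning("%s: skipped %d malformed junction lines", path, n_bad)
    return records


def filter_circular_junctions(
    junctions: list[ChimericJunction],
) -> list[ChimericJunction]:
    """Keep the circular-consistent subset, preserving input order."""
    return [j for j in junctions if j.circular_consistent]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_junctions(
    junctions: list[ChimericJunction],
    params: ClusterParams | None = None,
    sample_id: str = "",
    stats: ClusterStats | None = None,
) -> list[MicroDNACluster]:
    """Group circular-consistent junctions into microDNA clusters.

    Two junctions belong together when both their acceptor and their donor
    breakpoints lie within `extension` bp of each other; cluster membership
    is the transitive closure of that relation, which makes the outcome
    independent of input order. The cluster interval is
    [min acceptor, max donor); clusters below `min_support` unique reads or
    outside the [size_min, size_max] window are dropped (counts reported).
    """
    params = params or ClusterParams()
    junctions = [j for j in junctions if j.circular_consistent]
    if stats is not None:
        stats.n_circular += len(junctions)
    if not junctions:
        return []

    clusters: list[MicroDNACluster] = []
    n_drop_support = n_drop_size = n_raw = 0
    # group by (chrom, strand); transitive closure within each group via a
    # sort-by-acceptor sweep: the chaining relation needs both coordinates
    # within `extension`, so only acceptor-near pairs can ever relate
    by_key: dict[tuple[str, str], list[ChimericJunction]] = {}
    for j in junctions:
        by_key.setdefault((j.chrom_donor, j.strand_donor), []).append(j)
    for (chrom, _strand), group in sorted(by_key.items()):
        order = sorted(range(len(group)),
                       key=lambda i: (group[i].pos_acceptor, group[i].pos_donor))
        uf = _UnionFind(len(group))
        ext = params.extension
        for a in range(len(order)):
            i = order[a]
            for b in range(a + 1, len(order)):
                j = order[b]
                if group[j].pos_acceptor - group[i].pos_acceptor > ext:
                    break
                if abs(group[j].pos_donor - group[i].pos_donor) <= ext:
                    uf.union(i, j)
        members: dict[int, list[ChimericJunction]] = {}
        for i in range(len(group)):
            members.setdefault(uf.find(i), []).append(group[i])
        for comp in members.values():
            n_raw += 1
            start = min(j.pos_acceptor for j in comp)
            end = max(j.pos_donor for j in comp)
            read_ids = frozenset(j.read_id for j in comp)
            support = len(read_ids)
            if support < params.min_support:
                n_drop_support += 1
                continue
            length = end - start
            if not params.size_min <= length <= params.size_max:
                n_drop_size += 1
                continue
            clusters.append(
                MicroDNACluster(sample_id, GenomicInterval(chrom, start, end),
                                support, read_ids)
            )
    if stats is not None:
        stats.n_clusters_raw += n_raw
        stats.n_dropped_support += n_drop_support
        stats.n_dropped_size += n_drop_size
        stats.n_clusters += len(clusters)
    if n_drop_support or n_drop_size:
        logger.info(
            "dropped %d clusters below support %d and %d outside [%d, %d] bp",
            n_drop_support, params.min_support, n_drop_size,
            params.size_min, params.size_max,
        )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                 c.interval.end))
    return clusters


def call_clusters_from_file(
    path: str | Path,
    params: ClusterParams | None = None,
    sample_id: str = "",
    stats: ClusterStats | None = None,
) -> list[MicroDNACluster]:
    """parse -> filter -> cluster for one sample's junction file."""
    junctions = parse_chimeric_junctions(path)
    if stats is not None:
        stats.n_junctions += len(junctions)
    circ = filter_circular_junctions(junctions)
    return cluster_junctions(circ, params, sample_id=sample_id, stats=stats)


def island_method(
    sam_path: str | Path,
    params: ClusterParams | None = None,
    sample_id: str = "",
    min_clip: int = MIN_CLIP_LENGTH,
) -> list[MicroDNACluster]:
    """Circle calling from reads enclosed by identical soft-clips.

    A mapped read whose leading and trailing soft-clipped substrings are
    identical (exact match, >= min_clip nt) evidences a junction: the clip
    is the circle's tail read through the junction, so the nominated circle
    runs from the mapped segment's start to its end plus the clip length.
    Nominations are clustered exactly like chimeric junctions.
    """
    params = params or ClusterParams()
    nominations: list[ChimericJunction] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            cig = read.cigartuples
            if len(cig) < 3 or cig[0][0] != 4 or cig[-1][0] != 4:
                continue  # needs both a leading and a trailing soft-clip
            seq = read.query_sequence
            if seq is None:
                n_skipped += 1
                continue
            l_len, r_len = cig[0][1], cig[-1][1]
            if l_len != r_len or l_len < min_clip:
                continue
            if seq[:l_len] != seq[-r_len:]:
                continue
            start = read.reference_start
            end = read.reference_end + l_len  # clip wraps past the segment
            strand = "-" if read.is_reverse else "+"
            nominations.append(
                ChimericJunction(
                    read_id=read.query_name,
                    chrom_donor=read.reference_name,
                    pos_donor=end,
                    strand_donor=strand,
                    chrom_acceptor=read.reference_name,
                    pos_acceptor=start,
                    strand_acceptor=strand,
                )
            )
    if n_skipped:
        logger.warning("%s: %d soft-clipped reads lacked sequence", sam_path,
                       n_skipped)
    return cluster_junctions(nominations, params, sample_id=sample_id)


def write_clusters_bed(
    clusters: list[MicroDNACluster], path: str | Path
) -> None:
    """BED6: name = sample_id:cluster_idx, score = read support."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            name = f"{c.sample_id}:{i}" if c.sample_id else f"cluster:{i}"
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{name}\t{c.support}\t+\n"
            )
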