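"""Breakend calling: filtered alignments → deduplicated single-nucleotide breaks.

The fixed pipeline order is: MAPQ/soft-clip filtering → breakend
assignment → blacklist filtering → optical-duplicate removal. Because
library preparation is PCR-free, every retained read is one labelled
break end; the only duplicates to remove are *optical* ones — spurious
neighbouring clusters on the same flow-cell tile. Reads at the same
genomic position from different tiles or lanes are genuine recurrent
breaks from different cells and are always kept.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import AlignedRead, BreakEnd, GenomicInterval

__all__ = [
    "CallConfig",
    "CallStats",
    "filter_alignments",
    "assign_breakend",
    "apply_blacklist",
    "remove_optical_duplicates",
    "call_breakends",
]


@dataclass
class CallConfig:
    """Parameters of the breakend-calling pipeline.

    min_mapq
        Reads with mapping quality below this are discarded (default 30;
        ambiguous placements cannot support single-nucleotide break
        assignment).
    drop_softclipped
        Discard any read whose CIGAR contains an S operation: clipped
        ends make the 5′ terminus unreliable as a break coordinate.
    optical_dup_max_dist
        Euclidean pixel radius (same lane and tile) within which reads at
        an identical breakend position are considered one optical cluster.
    blacklist
        Strand-blind regions (poor mappability, chromosome ends,
        incomplete contigs) whose breakends are removed.
    """

    min_mapq: int = 30
    drop_softclipped: bool = True
    optical_dup_max_dist: int = 100
    blacklist: list[GenomicInterval] = field(default_factory=list)
    # Alternative breakend convention: take the base immediately 5' of the
    # read's first aligned base instead of the first aligned base itself.
    breakend_upstream_base: bool = False

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be non-negative")
        if self.optical_dup_max_dist < 0:
            raise ValueError("optical_dup_max_dist must be non-negative")


@dataclass
class CallStats:
    """Per-filter removal counts, reported so runs can be audited."""

    n_input: int = 0
    n_low_mapq: int = 0
    n_softclipped: int = 0
    n_blacklisted: int = 0
    n_optical_dups: int = 0
    n_no_flowcell: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def filter_alignments(
    reads, cfg: CallConfig | None = None, stats: CallStats | None = None
):
    """Yield reads passing the MAPQ and soft-clip filters."""
    cfg = cfg or CallConfig()
    for read in reads:
        if stats is not None:
            stats.n_input += 1
        if read.mapq < cfg.min_mapq:
            if stats is not None:
                stats.n_low_mapq += 1
            continue
        if cfg.drop_softclipped and read.has_softclip:
            if stats is not None:
                stats.n_softclipped += 1
            continue
        yield read


def assign_breakend(
    read: AlignedRead,
    sample_id: str = "",
    flowcell=None,
    upstream_base: bool = False,
) -> BreakEnd:
    """Reduce an aligned read to its single-nucleotide break position.

    The break sits at the 5′-terminal aligned base of the read: for a
    plus-strand read that is ``start``, for a minus-strand read
    ``end − 1``. With ``upstream_base=True`` the base immediately 5′ of
    the read is used instead (one coordinate outward on either strand).
    """
    if read.strand == "+":
        pos = read.start - 1 if upstream_base else read.start
    else:
        pos = read.end if upstream_base else read.end - 1
    return BreakEnd(
        chrom=read.chrom,
        pos=pos,
        strand=read.strand,
        sample_id=sample_id,
        read_id=read.read_id,
        flowcell=flowcell,
    )


def apply_blacklist(
    breakends,
    regions: list[GenomicInterval],
    stats: CallStats | None = None,
) -> list[BreakEnd]:
    """Drop breakends whose position falls in any region (strand-blind)."""
    if not regions:
        return list(breakends)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region in regions:
        trees[region.chrom].addi(region.start, region.end)
    kept = []
    for be in breakends:
        if be.chrom in trees and trees[be.chrom].overlaps_point(be.pos):
            if stats is not None:
                stats.n_blacklisted += 1
            continue
        kept.append(be)
    return kept


def remove_optical_duplicates(
    breakends,
    max_dist: int = 100,
    stats: CallStats | None = None,
) -> list[BreakEnd]:
    """Collapse optical-duplicate clusters to a single representative.

    Breakends sharing (sample, chrom, pos, strand, lane, tile) are
    single-linkage clustered under Euclidean pixel distance ≤ max_dist;
    each cluster keeps its lexicographically smallest (x, y) member so
    output is deterministic. Breakends without flow-cell coordinates
    bypass deduplication (counted in ``stats.n_no_flowcell``). Identical
    positions on different tiles or lanes — recurrent breaks from
    different cells — are never merged.

    Input order is not preserved; output is sorted by
    (chrom, pos, strand, read_id).
    """
    groups: dict[tuple, list[BreakEnd]] = defaultdict(list)
    kept: list[BreakEnd] = []
    for be in breakends:
        if be.flowcell is None:
            if stats is not None:
                stats.n_no_flowcell += 1
            kept.append(be)
            continue
        groups[
            (be.sample_id, be.chrom, be.pos, be.strand, be.flowcell.lane, be.flowcell.tile)
        ].append(be)

    for members in groups.values():
        if len(members) == 1:
            kept.append(members[0])
            continue
        for cluster in _single_linkage(members, max_dist):
            rep = min(cluster, key=lambda b: (b.flowcell.x, b.flowcell.y, b.read_id))
            kept.append(rep)
            if stats is not None:
                stats.n_optical_dups += len(cluster) - 1

    kept.sort(key=lambda b: (b.chrom, b.pos, b.strand, b.read_id))
    return kept


def _single_linkage(members: list[BreakEnd], max_dist: float) -> list[list[BreakEnd]]:
    """Union-find single-linkage clustering on flow-cell pixel distance."""
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    limit = max_dist * max_dist
    for i in range(n):
        fi = members[i].flowcell
        for j in range(i + 1, n):
            fj = members[j].flowcell
            dx, dy = fi.x - fj.x, fi.y - fj.y
            if dx * dx + dy * dy <= limit:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[BreakEnd]] = defaultdict(list)
    for i, be in enumerate(members):
        clusters[find(i)].append(be)
    return list(clusters.values())


def call_breakends(
    reads,
    cfg: CallConfig | None = None,
    sample_id: str = "",
    flowcell_of=None,
) -> tuple[list[BreakEnd], CallStats]:
    """Run the full calling pipeline on a stream of aligned reads.

    ``flowcell_of`` maps a read to its :class:`FlowcellCoord` (or None);
    by default the read name is parsed as an Illumina identifier and
    unparseable names leave the read exempt from optical deduplication.
    Returns breakends sorted by (chrom, pos, strand) plus removal stats.
    """
    from .io_formats import FormatError, parse_illumina_read_name

    cfg = cfg or CallConfig()
    stats = CallStats()

    if flowcell_of is None:

        def flowcell_of(read):
            try:
                return parse_illumina_read_name(read.read_id)
            except FormatError:
                return None

    breakends = [
        assign_breakend(
            read,
            sample_id=sample_id,
            flowcell=flowcell_of(read),
            upstream_base=cfg.breakend_upstream_base,
        )
        for read in filter_alignments(reads, cfg, stats)
    ]
    breakends = apply_blacklist(breakends, cfg.blacklist, stats)
    breakends = remove_optical_duplicates(breakends, cfg.optical_dup_max_dist, stats)
    stats.n_output = len(breakends)
    return breakends, stats
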