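"""Per-site break quantification, ranking and normalisation.

Counting is exact-integer throughout: a breakend is a width-1 interval,
a site an arbitrary half-open interval, and a breakend counts toward a
site iff its position lies inside and (optionally) the strands agree.
Cumulative percentages are computed from integer running sums and
converted to float only at the end, so the curve is invariant to
tie-break order and always terminates at exactly 100%.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import BreakEnd, GenomicInterval
from .sitefind import PredictedSite

__all__ = [
    "SiteBreakCount",
    "RecurrentBreak",
    "count_breaks_at_sites",
    "rank_and_cumulate",
    "breaks_per_cell",
    "breaks_per_million",
    "subsample_breakends",
    "recurrent_break_table",
    "site_set_overlap",
    "ranked_table",
]


def _interval_of(site) -> GenomicInterval:
    return site.interval if isinstance(site, PredictedSite) else site


@dataclass(frozen=True)
class SiteBreakCount:
    """A predicted site annotated with its overlapping-breakend count."""

    site: object  # PredictedSite or reduced GenomicInterval
    n_breaks: int
    rank: int = 0  # assigned by rank_and_cumulate; 1 = most breaks

    @property
    def interval(self) -> GenomicInterval:
        return _interval_of(self.site)


@dataclass(frozen=True)
class RecurrentBreak:
    """A breakend position collapsed across reads, treated vs control."""

    chrom: str
    pos: int
    strand: str
    n_treated: int
    n_control: int
    shared_with_control: bool


def count_breaks_at_sites(
    breakends: list[BreakEnd],
    sites: list,
    strand_match: bool = False,
) -> list[SiteBreakCount]:
    """Count breakends overlapping each site.

    A breakend counts toward a site iff pos ∈ [start, end) and, when
    ``strand_match`` is set, the strands agree (sites with strand '.'
    accept both). A breakend inside two overlapping sites counts toward
    both — double counting is visible as sum(counts) > len(breakends).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, site in enumerate(sites):
        iv = _interval_of(site)
        trees[iv.chrom].addi(iv.start, iv.end, idx)
    counts = [0] * len(sites)
    for be in breakends:
        if be.chrom not in trees:
            continue
        for hit in trees[be.chrom][be.pos]:
            iv = _interval_of(sites[hit.data])
            if strand_match and iv.strand != "." and iv.strand != be.strand:
                continue
            counts[hit.data] += 1
    return [SiteBreakCount(site=s, n_breaks=c) for s, c in zip(sites, counts)]


def rank_and_cumulate(
    counts: list[SiteBreakCount],
) -> tuple[list[SiteBreakCount], np.ndarray]:
    """Rank sites by break count and compute the cumulative-% curve.

    Sites are sorted by n_breaks descending, ties broken by
    (chrom, start) for deterministic output. The cumulative percentage
    at rank k is 100 × (breaks at ranks 1..k) / (total breaks): monotone
    non-decreasing, final value exactly 100 when any breaks exist.
    """
    ordered = sorted(
        counts, key=lambda c: (-c.n_breaks, c.interval.chrom, c.interval.start)
    )
    ranked = [
        SiteBreakCount(site=c.site, n_breaks=c.n_breaks, rank=i + 1)
        for i, c in enumerate(ordered)
    ]
    total = sum(c.n_breaks for c in ranked)
    if total == 0:
        return ranked, np.zeros(0)
    running = np.cumsum([c.n_breaks for c in ranked], dtype=np.int64)
    return ranked, running * 100.0 / total


def breaks_per_cell(total_breaks: int, n_cells: int):
    """Average breaks per cell: exact division of totals.

    With a digital readout the total read count equals the total number
    of labelled break ends, so e.g. 200 000 breaks over 100 000 cells is
    2.0 endogenous breaks per cell. Scale-invariant:
    breaks_per_cell(ka, kb) == breaks_per_cell(a, b).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if total_breaks < 0:
        raise ValueError("total_breaks must be non-negative")
    return total_breaks / n_cells


def breaks_per_million(n_breaks_at_sites: int, total_reads: int) -> float:
    """Nuclease-induced breaks per million sequenced reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if n_breaks_at_sites < 0:
        raise ValueError("n_breaks_at_sites must be non-negative")
    return n_breaks_at_sites / total_reads * 1e6


def subsample_breakends(
    breakends: list[BreakEnd],
    fraction: float,
    seed: int,
    exact: bool = False,
) -> list[BreakEnd]:
    """Keep each breakend independently with probability ``fraction``.

    Emulates sequencing fewer reads in silico: because one read is one
    break, per-site counts after subsampling are Binomial(n, f) and
    scale proportionally with f. ``exact=True`` instead draws exactly
    round(f·n) breakends without replacement (hypergeometric mode).
    Deterministic for a given seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return list(breakends)
    rng = np.random.default_rng(seed)
    if exact:
        k = int(round(fraction * len(breakends)))
        idx = sorted(rng.choice(len(breakends), size=k, replace=False))
        return [breakends[i] for i in idx]
    keep = rng.random(len(breakends)) < fraction
    return [be for be, k in zip(breakends, keep) if k]


def recurrent_break_table(
    treated_breakends: list[BreakEnd],
    control_breakends: list[BreakEnd],
    strand_aware: bool = True,
) -> list[RecurrentBreak]:
    """Collapse breakends by position and rank by treated recurrence.

    Positions seen at least once in both groups are flagged
    ``shared_with_control`` — candidates for endogenous fragile sites
    rather than induced breaks. Ranking is by treated count descending,
    ties by (chrom, pos, strand).
    """

    def key_of(be: BreakEnd):
        return be.key if strand_aware else (be.chrom, be.pos, ".")

    treated = Counter(key_of(be) for be in treated_breakends)
    control = Counter(key_of(be) for be in control_breakends)
    rows = [
        RecurrentBreak(
            chrom=chrom,
            pos=pos,
            strand=strand,
            n_treated=n,
            n_control=control.get((chrom, pos, strand), 0),
            shared_with_control=(chrom, pos, strand) in control,
        )
        for (chrom, pos, strand), n in treated.items()
    ]
    rows.sort(key=lambda r: (-r.n_treated, r.chrom, r.pos, r.strand))
    return rows


def site_set_overlap(site_lists: dict[str, list]) -> pd.DataFrame:
    """Membership matrix of interval collections under ≥1-bp overlap.

    For cross-method comparison of detected site lists: every interval
    from every collection becomes a row; column ``m`` is True when the
    interval overlaps (shares ≥1 bp with) any interval of collection
    ``m``. Aggregating identical boolean rows gives UpSet-style counts;
    pairwise shared counts are sums of pairwise conjunctions.
    """
    if len(site_lists) < 2:
        raise ValueError("need at least two site collections")
    names = list(site_lists)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, sites in site_lists.items():
        per_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for site in sites:
            iv = _interval_of(site)
            per_chrom[iv.chrom].addi(iv.start, iv.end)
        trees[name] = per_chrom

    rows = []
    for name, sites in site_lists.items():
        for site in sites:
            iv = _interval_of(site)
            flags = {
                other: bool(
                    iv.chrom in trees[other]
                    and trees[other][iv.chrom].overlap(iv.start, iv.end)
                )
                for other in names
            }
            rows.append(
                {"collection": name, "chrom": iv.chrom, "start": iv.start, "end": iv.end, **flags}
            )
    return pd.DataFrame(rows)


def ranked_table(ranked: list[SiteBreakCount], cum_pct: np.ndarray) -> pd.DataFrame:
    """Ranked per-site break table (site, n_breaks, rank, cum_pct) as TSV-ready frame."""
    return pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in ranked],
            "start": [c.interval.start for c in ranked],
            "end": [c.interval.end for c in ranked],
            "strand": [c.interval.strand for c in ranked],
            "n_breaks": [c.n_breaks for c in ranked],
            "rank": [c.rank for c in ranked],
            "cum_pct": cum_pct if len(cum_pct) else [0.0] * len(ranked),
        }
    )
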