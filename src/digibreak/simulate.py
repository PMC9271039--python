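"""Synthetic break-sequencing data with machine-readable ground truth.

Generates a random genome with planted nuclease target sites, simulates
per-cell cutting (each site cut independently per cell with its own
efficiency, endogenous background breaks as a per-cell Poisson process),
and emits one perfectly aligned read per break end, with Illumina-style
read names carrying flow-cell coordinates and optional injected optical
duplicates. Every break contributes exactly two breakends — one per
strand — at offsets fixed by the enzyme chemistry:

* ``blunt`` (Cas9-like): cut between motif offsets c−1 and c
  (default c = site length − PAM − 3, i.e. 3 bp upstream of the PAM),
  plus end at c, minus end at c−1.
* ``asisi_3prime_overhang``: 8-bp GCGATCGC site; after end blunting
  the plus end sits at 1-based in-site position 6, the minus end at
  position 3.
* ``hindiii_5prime_overhang``: 6-bp AAGCTT site with filled-in 4-nt
  5′ overhangs: plus end at 1-based position 2, minus end at position 5
  — two semi-overlapping symmetrical blocks of read starts.

Simplifications, deliberate: reads are error-free, fully mapped
(MAPQ 60) and never soft-clipped — the real pipeline delegates
alignment to external tools, so alignment noise is out of scope. Flow-
cell cluster coordinates are drawn on a 200-pixel grid so that distinct
simulated breaks can never fall within the optical-duplicate radius of
each other; injected duplicates are placed off-grid within 50 px of
their source read. All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io_formats import BreakEnd, GenomicInterval, write_fasta
from .sitefind import revcomp

__all__ = [
    "PlantedFamily",
    "PlantedSite",
    "SimConfig",
    "TrueBreak",
    "SimTruth",
    "make_genome",
    "simulate_breaks",
    "emit_reads",
    "write_sam",
    "run_simulation",
]

_CHEMISTRY_OFFSETS = {
    # motif-orientation 0-based offsets: (plus-strand end, minus-strand end)
    "asisi_3prime_overhang": (5, 2),
    "hindiii_5prime_overhang": (1, 4),
}

_GRID = 200  # px; > optical radius so grid points never single-link
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedFamily:
    """A sequence to embed ``count`` times, with its cut chemistry.

    ``chemistry`` None inherits the config default; ``cut_offset``
    (blunt only) is the motif offset c of the cut bond, default
    len − pam_len − 3 for Cas9-style sites, len//2 otherwise.
    ``efficiency`` None draws from the config efficiency model.
    """

    sequence: str
    count: int
    chemistry: str | None = None
    cut_offset: int | None = None
    pam_len: int = 3
    efficiency: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            raise ValueError("planted sequence must be over ACGT")
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class PlantedSite:
    """One embedded copy of a planted family, with its cut geometry."""

    family: int  # index into config planted families
    chrom: str
    start: int
    end: int
    strand: str  # orientation of embedding
    sequence: str  # family sequence (motif orientation)
    plus_end: int  # genome position of the plus-strand break end
    minus_end: int  # genome position of the minus-strand break end
    efficiency: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class SimConfig:
    """Study conditions for one simulated break-sequencing sample.

    Defaults mirror a desk-scale version of the assay: ~0.41 genomic GC,
    a skewed Beta(0.5, 2) spread of per-site cutting efficiencies (most
    sites cut rarely, a few near-always — the shape behind concave
    cumulative-frequency curves), 2 endogenous breaks per cell, 75-bp
    reads.
    """

    genome_length: int = 100_000
    gc_content: float = 0.41
    seed: int = 0
    planted_sites: list = field(default_factory=list)  # PlantedFamily or (seq, count)
    efficiency_model: tuple = ("beta", 0.5, 2.0)
    n_cells: int = 1000
    background_rate: float = 2.0
    read_length: int = 75
    optical_dup_rate: float = 0.0
    enzyme_chemistry: str = "blunt"
    chrom_name: str = "chrSim"
    margin: int = 200  # keep planted sites away from contig ends
    # endogenous fragile sites: (pos, per-cell break probability); planted
    # identically in treated and control configs to emulate recurrent
    # background breaks shared between samples
    fragile_sites: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0 <= self.optical_dup_rate <= 1:
            raise ValueError("optical_dup_rate must be in [0, 1]")
        if self.background_rate < 0 or self.n_cells < 0:
            raise ValueError("rates and counts must be non-negative")
        self.planted_sites = [
            fam if isinstance(fam, PlantedFamily) else PlantedFamily(fam[0], fam[1])
            for fam in self.planted_sites
        ]


@dataclass(frozen=True)
class TrueBreak:
    """One true break end: genome position, strand, cell, and provenance."""

    chrom: str
    pos: int
    strand: str
    cell: int
    source: int  # planted-site index, -1 = background, -2 = fragile site


@dataclass
class SimTruth:
    """Ground truth of a simulated sample."""

    sites: list[PlantedSite]
    cut_counts: list[int]  # per planted site, number of cells cut
    breakends: list[TrueBreak]  # two entries per cut / background break
    duplicate_read_ids: list[str] = field(default_factory=list)

    def true_breakend_multiset(self) -> dict[tuple[str, int, str], int]:
        from collections import Counter

        return dict(Counter((b.chrom, b.pos, b.strand) for b in self.breakends))


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _chemistry_ends(fam: PlantedFamily, default_chemistry: str) -> tuple[int, int]:
    """Motif-orientation offsets (plus_end, minus_end) for one family."""
    chem = fam.chemistry or default_chemistry
    if chem == "blunt":
        length = len(fam.sequence)
        c = fam.cut_offset
        if c is None:
            c = length - fam.pam_len - 3 if length > fam.pam_len + 6 else length // 2
        if not 1 <= c <= length - 1:
            raise ValueError(f"cut_offset {c} outside site of length {length}")
        return c, c - 1
    try:
        p_off, m_off = _CHEMISTRY_OFFSETS[chem]
    except KeyError:
        raise ValueError(f"unknown chemistry {chem!r}") from None
    expected = 8 if chem.startswith("asisi") else 6
    if len(fam.sequence) != expected:
        raise ValueError(f"{chem} requires a {expected}-bp site")
    return p_off, m_off


def make_genome(cfg: SimConfig) -> tuple[dict[str, str], list[PlantedSite]]:
    """Build the genome and plant the configured sites.

    Planting is rejection-checked: after embedding, no exact copy of any
    planted sequence (either orientation) exists anywhere except the
    planted loci; spurious background copies are resampled away. Planted
    copies are embedded in a random orientation, non-overlapping, at
    least ``margin`` bp from contig ends. Deterministic in cfg.seed.
    """
    rng_bases, rng_place, rng_eff = _rng_streams(cfg.seed, 3)

    probs = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    codes = rng_bases.choice(4, size=cfg.genome_length, p=probs)
    arr = _BASES[codes].copy()

    # place planted copies without overlap, away from the edges
    placements: list[tuple[int, int, int, str]] = []  # (family, start, end, strand)
    taken: list[tuple[int, int]] = []
    for fi, fam in enumerate(cfg.planted_sites):
        length = len(fam.sequence)
        for _copy in range(fam.count):
            for _attempt in range(10_000):
                start = int(
                    rng_place.integers(cfg.margin, cfg.genome_length - cfg.margin - length)
                )
                if all(start + length <= s or start >= e for s, e in taken):
                    break
            else:
                raise ValueError("cannot place planted sites without overlap")
            strand = "+" if rng_place.random() < 0.5 else "-"
            taken.append((start, start + length))
            placements.append((fi, start, start + length, strand))

    for fi, start, end, strand in placements:
        seq = cfg.planted_sites[fi].sequence
        embedded = seq if strand == "+" else revcomp(seq)
        arr[start:end] = np.frombuffer(embedded.encode(), dtype=np.uint8)

    # rejection-check: resample any spurious exact copy elsewhere
    planted_spans = {(s, e) for _f, s, e, _st in placements}
    queries = {fam.sequence for fam in cfg.planted_sites}
    queries |= {revcomp(q) for q in queries}
    for _round in range(100):
        genome_str = arr.tobytes().decode()
        spurious: list[tuple[int, int]] = []
        for q in sorted(queries):
            at = genome_str.find(q)
            while at != -1:
                span = (at, at + len(q))
                if span not in planted_spans and not any(
                    s < span[1] and span[0] < e for s, e in planted_spans
                ):
                    spurious.append(span)
                at = genome_str.find(q, at + 1)
        if not spurious:
            break
        for s, e in spurious:
            arr[s:e] = _BASES[rng_bases.choice(4, size=e - s, p=probs)]
    else:
        raise RuntimeError("could not eliminate spurious planted-sequence copies")

    genome = {cfg.chrom_name: arr.tobytes().decode()}

    sites: list[PlantedSite] = []
    for fi, start, end, strand in placements:
        fam = cfg.planted_sites[fi]
        p_off, m_off = _chemistry_ends(fam, cfg.enzyme_chemistry)
        length = end - start
        if strand == "+":
            plus_end, minus_end = start + p_off, start + m_off
        else:  # mirror: motif plus end maps to genome minus strand
            plus_end, minus_end = start + length - 1 - m_off, start + length - 1 - p_off
        if fam.efficiency is not None:
            eff = fam.efficiency
        elif cfg.efficiency_model[0] == "beta":
            eff = float(rng_eff.beta(cfg.efficiency_model[1], cfg.efficiency_model[2]))
        else:
            raise ValueError(f"unknown efficiency model {cfg.efficiency_model!r}")
        sites.append(
            PlantedSite(
                family=fi,
                chrom=cfg.chrom_name,
                start=start,
                end=end,
                strand=strand,
                sequence=fam.sequence,
                plus_end=plus_end,
                minus_end=minus_end,
                efficiency=eff,
            )
        )
    sites.sort(key=lambda s: s.start)
    return genome, sites


def simulate_breaks(cfg: SimConfig, sites: list[PlantedSite]) -> SimTruth:
    """Simulate per-cell cutting and endogenous background breaks.

    Each cell cuts each planted site independently with the site's
    efficiency; every cut emits two break ends at the chemistry offsets.
    Background breaks are Poisson(background_rate) per cell, uniform
    over the genome, blunt (two ends at k and k−1). Fragile sites are
    Bernoulli per cell at fixed positions, also blunt.
    """
    (rng,) = _rng_streams(cfg.seed, 5)[3:4]
    chrom = cfg.chrom_name
    breaks: list[TrueBreak] = []
    cut_counts = []
    for si, site in enumerate(sites):
        cut_cells = np.flatnonzero(rng.random(cfg.n_cells) < site.efficiency)
        cut_counts.append(int(cut_cells.size))
        for cell in cut_cells:
            breaks.append(TrueBreak(chrom, site.plus_end, "+", int(cell), si))
            breaks.append(TrueBreak(chrom, site.minus_end, "-", int(cell), si))
    if cfg.background_rate > 0:
        n_bg = rng.poisson(cfg.background_rate, size=cfg.n_cells)
        for cell, n in enumerate(n_bg):
            for pos in rng.integers(1, cfg.genome_length, size=n):
                pos = int(pos)
                breaks.append(TrueBreak(chrom, pos, "+", cell, -1))
                breaks.append(TrueBreak(chrom, pos - 1, "-", cell, -1))
    for pos, prob in cfg.fragile_sites:
        for cell in np.flatnonzero(rng.random(cfg.n_cells) < prob):
            breaks.append(TrueBreak(chrom, int(pos), "+", int(cell), -2))
            breaks.append(TrueBreak(chrom, int(pos) - 1, "-", int(cell), -2))
    return SimTruth(sites=sites, cut_counts=cut_counts, breakends=breaks)


@dataclass(frozen=True)
class SimRead:
    """An emitted read plus its flow-cell placement (pre-SAM form)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_duplicate: bool


def emit_reads(
    truth: SimTruth,
    cfg: SimConfig,
    genome: dict[str, str],
    sample_id: str = "sim",
) -> list[SimRead]:
    """One perfectly aligned read per true break end (plus duplicates).

    The read's 5′-terminal aligned base is the breakend: a plus-strand
    end at p yields a plus read [p, p+L); a minus-strand end at p yields
    a minus read [p−L+1, p+1); both truncated at contig boundaries.
    Read names follow the Illumina convention, with cluster coordinates
    on a 200-px grid; with probability ``optical_dup_rate`` a read gets
    an optical duplicate on the same tile within 50 px (recorded in
    ``truth.duplicate_read_ids``).
    """
    (rng,) = _rng_streams(cfg.seed, 5)[4:5]
    contig_len = {name: len(seq) for name, seq in genome.items()}
    used: set[tuple[int, int, int, int]] = set()
    reads: list[SimRead] = []

    def fresh_coord() -> tuple[int, int, int, int]:
        while True:
            lane = int(rng.integers(1, 5))
            tile = int(rng.integers(1101, 1109))
            x = _GRID * int(rng.integers(5, 250))
            y = _GRID * int(rng.integers(5, 250))
            if (lane, tile, x, y) not in used:
                used.add((lane, tile, x, y))
                return lane, tile, x, y

    def name_of(lane, tile, x, y) -> str:
        return f"SIM01:1:FC{sample_id}:{lane}:{tile}:{x}:{y}"

    for b in truth.breakends:
        clen = contig_len[b.chrom]
        if b.strand == "+":
            start, end = b.pos, min(b.pos + cfg.read_length, clen)
        else:
            start, end = max(b.pos + 1 - cfg.read_length, 0), b.pos + 1
        lane, tile, x, y = fresh_coord()
        reads.append(SimRead(name_of(lane, tile, x, y), b.chrom, start, end, b.strand, False))
        if cfg.optical_dup_rate > 0 and rng.random() < cfg.optical_dup_rate:
            while True:
                dx, dy = (int(d) for d in rng.integers(-50, 51, size=2))
                if (dx or dy) and (lane, tile, x + dx, y + dy) not in used:
                    break
            used.add((lane, tile, x + dx, y + dy))
            dup_id = name_of(lane, tile, x + dx, y + dy)
            reads.append(SimRead(dup_id, b.chrom, start, end, b.strand, True))
            truth.duplicate_read_ids.append(dup_id)
    return reads


def sim_reads_as_alignments(reads: list[SimRead]):
    """Convert emitted reads to AlignedRead records (MAPQ 60, all-match CIGAR)."""
    from .io_formats import AlignedRead

    return [
        AlignedRead(
            read_id=r.read_id,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            strand=r.strand,
            mapq=60,
            has_softclip=False,
            cigar=f"{r.end - r.start}M",
        )
        for r in reads
    ]


def write_sam(
    reads: list[SimRead], genome: dict[str, str], path: str | Path
) -> None:
    """Write emitted reads as a plain-text SAM with proper header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    refs = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = refs[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{r.end - r.start}M"
            a.flag = 16 if r.strand == "-" else 0
            seq = genome[r.chrom][r.start : r.end]
            if r.strand == "-":
                seq = revcomp(seq)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def run_simulation(cfg: SimConfig, outdir: str | Path, sample_id: str = "sim"):
    """Full simulation to disk: genome.fa, sites.bed, truth_breaks.bed, reads.sam, truth.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, sites = make_genome(cfg)
    truth = simulate_breaks(cfg, sites)
    reads = emit_reads(truth, cfg, genome, sample_id=sample_id)

    write_fasta(genome, outdir / "genome.fa")
    with open(outdir / "sites.bed", "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tfamily{s.family}\t"
                f"{s.efficiency:.4f}\t{s.strand}\n"
            )
    with open(outdir / "truth_breaks.bed", "w") as fh:
        for b in truth.breakends:
            fh.write(f"{b.chrom}\t{b.pos}\t{b.pos + 1}\tcell{b.cell}\t{b.source}\t{b.strand}\n")
    write_sam(reads, genome, outdir / "reads.sam")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "cut_counts": truth.cut_counts,
                "n_true_breakends": len(truth.breakends),
                "n_duplicates": len(truth.duplicate_read_ids),
                "sites": [
                    {
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "strand": s.strand,
                        "family": s.family,
                        "efficiency": s.efficiency,
                        "plus_end": s.plus_end,
                        "minus_end": s.minus_end,
                    }
                    for s in sites
                ],
            },
            fh,
            indent=1,
        )
    return genome, sites, truth, reads
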