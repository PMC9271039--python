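# Methods

## Data model

All coordinates are 0-based half-open (BED-native) internally; SAM's
1-based coordinates are converted at the parser boundary, and 1-based
values appear only in human-readable reports (e.g. the "in-site
position 6/3" AsiSI offsets). A breakend is a width-1 interval with a
definite strand; blacklist intervals may carry strand `.` and are
applied strand-blind.

## Breakend calling

Pipeline order is fixed: MAPQ/soft-clip filter → breakend assignment →
blacklist → optical deduplication, with output sorted by
(chrom, pos, strand).

**Breakend convention.** The break is assigned to the 5′-terminal
*aligned* base of the read: `+` read → alignment start, `−` read →
end − 1. The alternative reading — the base immediately 5′ *of* the
read — is available via `CallConfig(breakend_upstream_base=True)`. The
default is the convention consistent with AsiSI chemistry: AsiSI cuts
`GCGAT^CGC` leaving 2-nt 3′ overhangs, and after end blunting the
plus-strand read 5′ ends fall at 1-based in-site position 6 and the
minus-strand ends at position 3, which is exactly what the default
convention recovers (and what the site-reduction step predicts).

**Optical deduplication.** Breakends sharing
(sample, chrom, pos, strand, lane, tile) are single-linkage clustered
under Euclidean pixel distance ≤ `optical_dup_max_dist` (default
100 px — no published threshold exists for this step, so the default
mirrors common duplicate-marking practice and is configurable). Each
cluster keeps its lexicographically smallest (x, y) member, making runs
bit-reproducible. Same-position breakends on different tiles or lanes
are never merged: with a digital readout those are recurrent breaks
from different cells, the signal of interest. Reads without parseable
Illumina names are kept but exempt from deduplication (counted in the
stats) — conservative, never silently dropping data. The operation is
idempotent and never changes the set of distinct (chrom, pos, strand)
keys, only multiplicities. PCR/UMI duplicate correction is deliberately
absent: the assay is PCR-free.

**Soft-clip rule.** Any `S` in the CIGAR removes the read (whole-read
removal, not clip trimming), since a clipped 5′ end invalidates the
break coordinate.

## Site finding

Motif search is pure fixed-length Hamming distance — no indels or
bulges — implemented as a vectorised per-offset comparison over the
encoded sequence; an independent naive per-window scan (tests) verifies
it. Genome letters outside ACGT never match any motif base (windows
containing N are excluded outright), keeping assembly gaps and
chromosome ends out of the site lists. Palindromic motifs (AAGCTT,
GCGATCGC) match identically on both strands at every locus, so they are
reported once per locus in forward orientation by default; per-site
break counts then aggregate both strands' breakends, which is the
quantity of interest ("breaks per site", not per orientation).

HindIII quantification uses the full 6-bp site interval for overlap;
the 1-bp reduction is specific to the AsiSI analysis, where
strand-matched overlap with position 6 (+) / 3 (−) defines a genuine
induced break. The Cas9 cut window for a protospacer+PAM site is the
2-bp interval spanning the blunt cut 3 bp upstream of the PAM
([s+16, s+18) for a plus-oriented 20+3 site; mirrored for minus), with
strand `.` because both ends of a blunt cut fall inside it.

## Quantification

Counting is exact-integer; cumulative percentages are computed from
integer running sums and converted to float at output, so curves are
invariant to tie-break order and end at exactly 100%. Ranking ties are
broken by (chrom, start) for deterministic files. A breakend inside two
overlapping sites counts toward both (double counting is auditable as
column sums). Subsampling is per-breakend Bernoulli by default —
mirroring "sequence fewer reads" — with an exact-count mode available;
per-site counts after subsampling are Binomial(n, f), hence directly
proportional to f, which the proportionality tests verify by
regression. The recurrent-break table is strand-aware by default
(strand-blind behind a flag).

## Off-target discovery

Mismatches in the spacer and PAM are pooled into one total: the N of
NGG is free, each non-G at the two G positions adds 1. The seed is the
12 protospacer nucleotides proximal to the PAM. Cut-window overlap is
strand-blind (requiring strand match would halve sensitivity for a
blunt cut; strand matching is an AsiSI-specific rule). The recurrence
rule counts breaks per sample, not pooled across samples.

The empirical FDR per filter condition is F/(T+F), where T and F are
the distinct candidate loci called in the treated and control sample
groups respectively (union over replicates by default; intersection
behind a flag). F/T is available as an alternative formula. A
documented consequence of F/(T+F): feeding identical breakends as
treated and control gives exactly 1/2 wherever anything is called.
Condition selection maximises T subject to FDR ≤ α, ties broken toward
the strictest condition (smallest total, then seed, then recurrence
budget) so the choice is deterministic.

## Simulator

The generator emulates the study conditions of the assay: a uniform
random genome at 41% GC (human-like) with planted sites embedded in
random orientation, non-overlapping, rejection-checked so no spurious
exact copy of a planted sequence exists elsewhere; per-site cutting
efficiencies drawn from Beta(0.5, 2) by default — a skewed spread where
most sites cut rarely and a few near-always, reproducing the concave
cumulative break-frequency curves seen in real per-site data; per-cell
Bernoulli cutting; endogenous background as Poisson(2) breaks per cell
(the measured endogenous level of ~2 breaks per cell), uniform in
position. Every break emits exactly two ends, one per strand, at
chemistry-determined offsets:

| chemistry | site | plus end (1-based in-site) | minus end |
|---|---|---|---|
| `asisi_3prime_overhang` | GCGATCGC (8 bp) | 6 | 3 |
| `hindiii_5prime_overhang` | AAGCTT (6 bp) | 2 | 5 |
| `blunt` (Cas9-like) | protospacer+PAM | cut offset c | c − 1 |

The AsiSI offsets are the published reduction values; the HindIII
offsets are a modelling choice (filled-in 4-nt 5′ overhang giving two
semi-overlapping symmetrical read-start blocks), since exact offsets
are not printed anywhere — they are used only inside the simulator.
Background breaks are blunt. Fragile-site mode plants recurrent
per-cell Bernoulli breaks at fixed positions, used to emulate
endogenous hotspots shared between treated and control samples.

Reads are error-free, fully aligned (MAPQ 60, all-match CIGAR), one per
break end, 5′-anchored at the breakend and truncated at contig
boundaries. Flow-cell coordinates are drawn without replacement on a
200-px grid — twice the optical radius — so two distinct simulated
breaks can never single-link, making truth recovery exact by
construction; injected optical duplicates are placed off-grid within
50 px of their source on the same tile, so they always collapse back.
Real flow cells are not gridded: this is the one deliberate departure
from realism, trading cluster-position realism for an exact,
seed-stable ground truth. Consequently passing the digital-identity
tests shows the pipeline is exactly lossless on ideal data; it says
nothing about alignment noise, sequencing error, or borderline optical
clusters at the threshold, none of which the generator emulates. All
randomness derives from the single config seed (separate spawned
streams for genome, breaks and reads); identical configs give
byte-identical output files.

## Test and reference problem sizes

The end-to-end identity checks run on a 1 Mb genome with 20 planted
AsiSI-chemistry sites, 5 000 cells, Beta(0.5, 2) efficiencies and 2
background breaks per cell (~60 k reads); the optical-duplicate check
uses 500 kb, 2 000 cells and a 10% duplicate rate; scanner/oracle
equivalence uses 100 random 100-kb sequences; the off-target FDR
scenario uses a 100 kb genome, 400 cells, an EMX1-like guide with
planted true off-targets (≤3 total, ≤2 seed mismatches) and seed-4
decoy sites carrying shared fragile breaks. These sizes give exact or
well-powered checks while keeping the suite fast.

## Known limitations

- Hamming-only search: RNA/DNA bulges and indels are not modelled.
- The blacklist is applied strand-blind; no curated blacklist ships
  with the package (any BED is accepted).
- FDR is empirical and sample-level; no per-site statistical test is
  performed between conditions.
- The simulator does not model sequencing error, mappability, or PCR
  amplification (the assay is PCR-free by design).
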