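"""Mismatch-tolerant nuclease target-site mapping.

Finds genomic occurrences of enzyme recognition motifs (HindIII AAGCTT,
AsiSI GCGATCGC, or any fixed-length motif) within a Hamming-distance
budget, and reduces found sites to the coordinates where break ends are
expected. Mismatch counting is pure Hamming — fixed-length windows, no
indels — and windows containing non-ACGT letters (assembly gaps, IUPAC
ambiguity codes) never match, which keeps chromosome-end artifacts out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomicInterval

__all__ = [
    "PredictedSite",
    "locate_motif",
    "reduce_asisi_site",
    "exclude_chromosomes",
    "crispr_cut_window",
    "revcomp",
    "ASISI_MOTIF",
    "HINDIII_MOTIF",
]

ASISI_MOTIF = "GCGATCGC"
HINDIII_MOTIF = "AAGCTT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base → small integer code; anything outside ACGT maps to 4 and can
# never match a motif base.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
# N in a *pattern* (PAM wildcard) matches any real base.
_WILDCARD = 5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_pattern(pattern: str) -> np.ndarray:
    """Encode a search pattern; N is a wildcard matching any ACGT base."""
    codes = encode(pattern).copy()
    codes[np.frombuffer(pattern.encode("ascii"), dtype=np.uint8) == ord("N")] = _WILDCARD
    return codes


@dataclass(frozen=True)
class PredictedSite:
    """A genomic occurrence of a motif (or protospacer+PAM) match.

    ``matched_seq`` is the genomic sequence read in the motif's
    orientation (reverse-complemented for minus-strand sites), so it is
    directly comparable with the query motif.
    """

    interval: GenomicInterval
    matched_seq: str
    n_mismatch: int

    def __post_init__(self) -> None:
        if len(self.matched_seq) != len(self.interval):
            raise ValueError("matched_seq length must equal interval length")
        if self.n_mismatch < 0:
            raise ValueError("n_mismatch must be non-negative")


def mismatch_profile(codes: np.ndarray, pattern_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of every window of ``codes`` against the pattern.

    Non-ACGT genome letters incur a +100 penalty so no finite budget
    admits them; pattern wildcards (code 5) match any real base.
    """
    m = len(pattern_codes)
    n = len(codes) - m + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j, pc in enumerate(pattern_codes):
        window = codes[j : j + n]
        bad = window == 4
        if pc == _WILDCARD:
            mm += 100 * bad
        else:
            mm += (window != pc) + 99 * bad
    return mm


def locate_motif(
    genome: dict[str, str],
    motif: str,
    max_mm: int = 0,
    dedupe_palindrome: bool | None = None,
) -> list[PredictedSite]:
    """Find all windows within ``max_mm`` Hamming mismatches of ``motif``.

    Both strands are scanned; minus-strand hits are reported with
    strand '−' and a reverse-complemented ``matched_seq``. For
    palindromic motifs every locus would appear once per orientation
    with identical mismatch count, so by default (``dedupe_palindrome
    =None`` → auto) palindromes are reported once per locus in forward
    orientation; per-site break counts then aggregate both strands'
    breakends.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not 0 <= max_mm < len(motif):
        raise ValueError("max_mm must satisfy 0 ≤ max_mm < len(motif)")

    is_palindrome = revcomp(motif) == motif
    if dedupe_palindrome is None:
        dedupe_palindrome = is_palindrome

    fwd = encode_pattern(motif)
    rev = encode_pattern(revcomp(motif))
    sites: list[PredictedSite] = []
    for chrom, seq in genome.items():
        codes = encode(seq)
        fwd_mm = mismatch_profile(codes, fwd)
        for start in np.flatnonzero(fwd_mm <= max_mm):
            start = int(start)
            window = seq[start : start + len(motif)]
            sites.append(
                PredictedSite(
                    GenomicInterval(chrom, start, start + len(motif), "+"),
                    window,
                    int(fwd_mm[start]),
                )
            )
        if not (is_palindrome and dedupe_palindrome):
            rev_mm = mismatch_profile(codes, rev)
            for start in np.flatnonzero(rev_mm <= max_mm):
                start = int(start)
                window = seq[start : start + len(motif)]
                sites.append(
                    PredictedSite(
                        GenomicInterval(chrom, start, start + len(motif), "-"),
                        revcomp(window),
                        int(rev_mm[start]),
                    )
                )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.strand))
    return sites


def reduce_asisi_site(site: PredictedSite | GenomicInterval) -> tuple[GenomicInterval, GenomicInterval]:
    """Reduce an 8-bp AsiSI site to its two expected 1-bp breakend intervals.

    AsiSI cleaves GCGAT^CGC leaving 2-nt 3′ overhangs; after end
    blunting the labelled break ends sit at 1-based in-site position 6
    on the plus strand and position 3 on the minus strand. Returns
    (plus_interval, minus_interval), both width 1, strictly inside the
    site.
    """
    iv = site.interval if isinstance(site, PredictedSite) else site
    if len(iv) != 8:
        raise ValueError(f"AsiSI site must be 8 bp, got {len(iv)}")
    plus = GenomicInterval(iv.chrom, iv.start + 5, iv.start + 6, "+")
    minus = GenomicInterval(iv.chrom, iv.start + 2, iv.start + 3, "-")
    return plus, minus


def exclude_chromosomes(sites: list, chroms: set[str]) -> list:
    """Drop sites on the listed chromosomes (e.g. chrY for female lines)."""

    def chrom_of(site):
        return site.interval.chrom if isinstance(site, PredictedSite) else site.chrom

    return [s for s in sites if chrom_of(s) not in chroms]


def crispr_cut_window(site: PredictedSite | GenomicInterval, pam_len: int = 3) -> GenomicInterval:
    """The 2-bp interval flanking the expected Cas9 break of a site.

    Cas9 cuts bluntly 3 bp upstream of the PAM, between protospacer
    bases 17 and 18 (for a 20-nt spacer): the window covers those two
    bases. For a plus-orientation site (protospacer then PAM) starting
    at s with spacer length L this is [s+L−4, s+L−2); minus-orientation
    sites (PAM first, in genome coordinates) mirror to
    [s+pam_len+2, s+pam_len+4). Strand is '.' — both ends of a blunt
    cut fall inside the window.
    """
    iv = site.interval if isinstance(site, PredictedSite) else site
    if len(iv) < pam_len + 4:
        raise ValueError(f"site of length {len(iv)} too short for pam_len {pam_len}")
    spacer_len = len(iv) - pam_len
    if iv.strand == "-":
        start = iv.start + pam_len + 2
    else:
        start = iv.start + spacer_len - 4
    return GenomicInterval(iv.chrom, start, start + 2, ".")
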