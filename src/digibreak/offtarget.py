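"""CRISPR off-target discovery with an empirical FDR filter matrix.

The procedure: enumerate every genomic protospacer+PAM window within a
total-mismatch budget of the guide (6 or 7, spacer and canonical PAM
combined), filter by seed-region mismatches (the 12 nt proximal to the
PAM, where mismatches most strongly abolish cutting: budgets 2–5),
intersect each candidate's 2-bp expected cut window with called
breakends, and apply a recurrence rule — candidates with more than *n*
mismatches need more than one overlapping break to be retained. The
2 × 4 × 4 grid of (total, seed, recurrence) budgets gives 32 filter
conditions per sample; treated-vs-control comparison yields an
empirical FDR per condition, and the selected condition maximises
treated yield subject to an FDR ceiling.

PAM mismatch counting: the N of NGG matches any base (0 mm); each
non-G at the two G positions adds 1, pooled with spacer mismatches
into the single total.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .io_formats import BreakEnd, GenomicInterval
from .sitefind import crispr_cut_window, encode, encode_pattern, mismatch_profile, revcomp

__all__ = [
    "GuideSpec",
    "CandidateSite",
    "FilterCondition",
    "OffTargetCall",
    "STANDARD_GRID",
    "enumerate_candidates",
    "seed_filter",
    "call_offtargets",
    "run_filter_matrix",
    "fdr_by_condition",
    "select_condition",
    "standard_conditions",
    "mismatch_alignment",
]

SEED_LEN = 12  # PAM-proximal nucleotides of the protospacer

# the standard filter-matrix axes: 2 total-mm × 4 seed-mm × 4 recurrence
STANDARD_GRID = {
    "max_total_mm": (6, 7),
    "max_seed_mm": (2, 3, 4, 5),
    "recurrence_n": (2, 3, 4, 5),
}


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA spacer plus PAM pattern (N = wildcard)."""

    spacer: str
    pam: str = "NGG"
    name: str = "guide"

    def __post_init__(self) -> None:
        spacer = self.spacer.upper().replace("U", "T")
        object.__setattr__(self, "spacer", spacer)
        object.__setattr__(self, "pam", self.pam.upper())
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer must be over ACGT, got {self.spacer!r}")
        if set(self.pam) - set("ACGTN"):
            raise ValueError(f"PAM pattern must be over ACGTN, got {self.pam!r}")

    @property
    def site_len(self) -> int:
        return len(self.spacer) + len(self.pam)


@dataclass(frozen=True)
class CandidateSite:
    """A genomic protospacer+PAM window within the mismatch budget."""

    interval: GenomicInterval  # oriented: '+' = protospacer then PAM
    site_seq: str  # in guide orientation (protospacer + PAM)
    n_mismatch_total: int
    n_mismatch_seed: int
    cut_window: GenomicInterval  # 2 bp, strand '.'

    def __post_init__(self) -> None:
        if self.n_mismatch_seed > self.n_mismatch_total:
            raise ValueError("seed mismatches cannot exceed total mismatches")

    @property
    def locus(self) -> tuple[str, int, int, str]:
        return (
            self.interval.chrom,
            self.interval.start,
            self.interval.end,
            self.interval.strand,
        )


@dataclass(frozen=True, order=True)
class FilterCondition:
    """One cell of the filter matrix.

    ``recurrence_n`` is the mismatch value *n* of the recurrence rule:
    candidates with total mismatches > n need more than one overlapping
    break. Dataclass ordering (total, seed, recurrence) ascending =
    strictest first, used for deterministic tie-breaking.
    """

    max_total_mm: int
    max_seed_mm: int
    recurrence_n: int


@dataclass(frozen=True)
class OffTargetCall:
    """A candidate site retained under a filter condition."""

    candidate: CandidateSite
    n_breaks: int
    condition: FilterCondition
    sample_id: str = ""


def standard_conditions() -> list[FilterCondition]:
    """The full 32-member filter grid, strictest first."""
    return [
        FilterCondition(t, s, r)
        for t, s, r in product(
            STANDARD_GRID["max_total_mm"],
            STANDARD_GRID["max_seed_mm"],
            STANDARD_GRID["recurrence_n"],
        )
    ]


def enumerate_candidates(
    genome: dict[str, str],
    guide: GuideSpec,
    max_total_mm: int = 6,
    expected_spacer_len: int | None = 20,
) -> list[CandidateSite]:
    """Find all protospacer+PAM windows within the total mismatch budget.

    Scans both strands; mismatches in the spacer and against the PAM
    pattern are pooled (wildcard PAM positions are free). Each
    candidate carries its seed mismatch count and its expected 2-bp cut
    window. ``expected_spacer_len`` guards against truncated guides;
    pass None to allow non-standard lengths.
    """
    if expected_spacer_len is not None and len(guide.spacer) != expected_spacer_len:
        raise ValueError(
            f"spacer length {len(guide.spacer)} != expected {expected_spacer_len}"
        )
    pattern = guide.spacer + guide.pam
    m = len(pattern)
    fwd = encode_pattern(pattern)
    rev = encode_pattern(revcomp(pattern))
    # seed = PAM-proximal 12 nt of the spacer
    seed_lo = len(guide.spacer) - SEED_LEN  # pattern coords, forward
    seed_hi = len(guide.spacer)

    out: list[CandidateSite] = []
    for chrom, seq in genome.items():
        codes = encode(seq)
        for strand, pat in (("+", fwd), ("-", rev)):
            mm = mismatch_profile(codes, pat)
            for start in np.flatnonzero(mm <= max_total_mm):
                start = int(start)
                window = seq[start : start + m]
                site_seq = window if strand == "+" else revcomp(window)
                n_seed = sum(
                    1
                    for j in range(seed_lo, seed_hi)
                    if site_seq[j] != guide.spacer[j]
                )
                interval = GenomicInterval(chrom, start, start + m, strand)
                out.append(
                    CandidateSite(
                        interval=interval,
                        site_seq=site_seq,
                        n_mismatch_total=int(mm[start]),
                        n_mismatch_seed=n_seed,
                        cut_window=crispr_cut_window(interval, pam_len=len(guide.pam)),
                    )
                )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    return out


def seed_filter(candidates: list[CandidateSite], max_seed_mm: int) -> list[CandidateSite]:
    """Retain candidates with at most ``max_seed_mm`` seed mismatches."""
    return [c for c in candidates if c.n_mismatch_seed <= max_seed_mm]


def count_breaks_in_window(breakends: list[BreakEnd], window: GenomicInterval) -> int:
    """Breakends with pos inside the window, strand-blind (both blunt ends count)."""
    return sum(
        1 for be in breakends if window.contains(be.chrom, be.pos)
    )


def call_offtargets(
    candidates: list[CandidateSite],
    breakends: list[BreakEnd],
    condition: FilterCondition,
    sample_id: str = "",
) -> list[OffTargetCall]:
    """Apply the break-overlap and recurrence rule under one condition.

    A candidate (already within the condition's total and seed budgets)
    is called iff ≥1 breakend falls in its 2-bp cut window AND either
    its total mismatches ≤ recurrence_n or more than one break overlaps
    — a single break supports only close-to-guide sites; degenerate
    sites must recur.
    """
    from collections import defaultdict

    by_pos: dict[tuple[str, int], int] = defaultdict(int)
    for be in breakends:
        by_pos[(be.chrom, be.pos)] += 1

    calls = []
    for cand in candidates:
        if cand.n_mismatch_total > condition.max_total_mm:
            continue
        if cand.n_mismatch_seed > condition.max_seed_mm:
            continue
        w = cand.cut_window
        n = by_pos.get((w.chrom, w.start), 0) + by_pos.get((w.chrom, w.start + 1), 0)
        if n >= 1 and (cand.n_mismatch_total <= condition.recurrence_n or n > 1):
            calls.append(
                OffTargetCall(candidate=cand, n_breaks=n, condition=condition, sample_id=sample_id)
            )
    return calls


def run_filter_matrix(
    candidates: list[CandidateSite],
    breakends_by_sample: dict[str, list[BreakEnd]],
    conditions: list[FilterCondition] | None = None,
) -> dict[tuple[str, FilterCondition], list[OffTargetCall]]:
    """All (sample × condition) call sets for the filter grid.

    ``candidates`` is the widest enumeration (e.g. total mm ≤ 7); each
    condition re-applies its own total and seed budgets, reproducing the
    8 seed-filtered candidate sets × 4 recurrence values = 32 datasets
    per sample. Call sets are monotone non-decreasing along each
    relaxation axis of the grid.
    """
    conditions = conditions if conditions is not None else standard_conditions()
    out = {}
    for sample_id, breakends in breakends_by_sample.items():
        for cond in conditions:
            out[(sample_id, cond)] = call_offtargets(
                candidates, breakends, cond, sample_id=sample_id
            )
    return out


def fdr_by_condition(
    matrix_calls: dict[tuple[str, FilterCondition], list[OffTargetCall]],
    treated_samples: list[str],
    control_samples: list[str],
    replicate_rule: str = "union",
    fdr_formula: str = "f_over_t_plus_f",
) -> pd.DataFrame:
    """Empirical FDR per filter condition from treated vs control samples.

    True positives are sites identified across the treated sample group,
    false positives those identified across the untreated control group
    (controls received no guide, so any call there is background).
    ``replicate_rule``: 'union' (a site counts if called in any replicate)
    or 'intersection' (must be called in every replicate).
    ``fdr_formula``: 'f_over_t_plus_f' → F/(T+F); 'f_over_t' → F/T.
    """
    if not treated_samples or not control_samples:
        raise ValueError("need at least one treated and one control sample")
    conditions = sorted({cond for (_s, cond) in matrix_calls})

    def group_sites(samples: list[str], cond: FilterCondition) -> set:
        per_sample = [
            {call.candidate.locus for call in matrix_calls.get((s, cond), [])}
            for s in samples
        ]
        if replicate_rule == "union":
            return set().union(*per_sample)
        if replicate_rule == "intersection":
            return set.intersection(*per_sample)
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")

    rows = []
    for cond in conditions:
        t = len(group_sites(treated_samples, cond))
        f = len(group_sites(control_samples, cond))
        if fdr_formula == "f_over_t_plus_f":
            fdr = f / (t + f) if t + f else 0.0
        elif fdr_formula == "f_over_t":
            fdr = f / t if t else (0.0 if f == 0 else float("inf"))
        else:
            raise ValueError(f"unknown fdr_formula {fdr_formula!r}")
        rows.append(
            {
                "max_total_mm": cond.max_total_mm,
                "max_seed_mm": cond.max_seed_mm,
                "recurrence_n": cond.recurrence_n,
                "n_treated_sites": t,
                "n_control_sites": f,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)


def select_condition(fdr_table: pd.DataFrame, alpha: float = 0.05) -> FilterCondition:
    """Pick the condition maximising treated yield subject to FDR ≤ alpha.

    Ties are broken toward the strictest condition (smallest total, then
    seed, then recurrence budget). If no condition satisfies alpha the
    minimal-FDR condition is returned (same tie-break) — callers should
    treat that as a warning sign.
    """
    if fdr_table.empty:
        raise ValueError("empty FDR table")
    df = fdr_table.sort_values(
        ["max_total_mm", "max_seed_mm", "recurrence_n"]
    ).reset_index(drop=True)
    ok = df[df["fdr"] <= alpha]
    if ok.empty:
        import warnings

        warnings.warn(
            f"no filter condition reaches FDR ≤ {alpha}; returning minimal-FDR condition",
            stacklevel=2,
        )
        best = df.loc[df["fdr"].idxmin()]
    else:
        best = ok.loc[ok["n_treated_sites"].idxmax()]
    return FilterCondition(
        int(best["max_total_mm"]), int(best["max_seed_mm"]), int(best["recurrence_n"])
    )


def mismatch_alignment(guide: GuideSpec, candidates: list[CandidateSite]) -> str:
    """Text alignment of candidate sites against the guide.

    Matching bases are shown as dots, mismatches as the genomic base —
    the usual off-target report layout.
    """
    pattern = guide.spacer + guide.pam
    lines = [f"{pattern}  (guide {guide.name}: spacer+PAM)"]
    for cand in candidates:
        row = "".join(
            "." if (p == "N" or s == p) else s
            for s, p in zip(cand.site_seq, pattern)
        )
        iv = cand.interval
        lines.append(
            f"{row}  {iv.chrom}:{iv.start}-{iv.end}({iv.strand}) "
            f"mm={cand.n_mismatch_total} seed={cand.n_mismatch_seed}"
        )
    return "\n".join(lines)
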