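import numpy as np
import pandas as pd
import pytest

from digibreak.io_formats import BreakEnd, GenomicInterval
from digibreak.offtarget import (
    CandidateSite,
    FilterCondition,
    GuideSpec,
    call_offtargets,
    enumerate_candidates,
    fdr_by_condition,
    mismatch_alignment,
    run_filter_matrix,
    seed_filter,
    select_condition,
    standard_conditions,
)
from digibreak.sitefind import revcomp

from _oracles import brute_force_motif_scan
from conftest import random_genome

SPACER = "GAGTCCGAGCAGAAGAAGAA"  # EMX1
GUIDE = GuideSpec(spacer=SPACER, pam="NGG", name="EMX1")


def embed(*seqs, pad=300, seed=0):
    """Genome with each sequence embedded at a known, spaced position."""
    rng = np.random.default_rng(seed)
    parts, positions, at = [], [], 0
    for s in seqs:
        filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=pad)])
        parts += [filler, s]
        at += pad
        positions.append(at)
        at += len(s)
    parts.append("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=pad)]))
    return {"g": "".join(parts)}, positions


def be_at(chrom, pos, n=1, strand="+", sample="t1"):
    return [
        BreakEnd(chrom, pos, strand, sample_id=sample, read_id=f"r{pos}_{i}")
        for i in range(n)
    ]


class TestEnumerateCandidates:
    def test_exact_on_target(self):
        genome, (pos,) = embed(SPACER + "AGG")
        cands = enumerate_candidates(genome, GUIDE, max_total_mm=3)
        exact = [c for c in cands if c.n_mismatch_total == 0]
        assert len(exact) == 1
        c = exact[0]
        assert c.interval.start == pos and c.n_mismatch_seed == 0
        assert c.cut_window == GenomicInterval("g", pos + 16, pos + 18, ".")

    def test_pam_n_position_is_free(self):
        for pam_base in "ACGT":
            genome, _ = embed(SPACER + pam_base + "GG", seed=3)
            cands = enumerate_candidates(genome, GUIDE, max_total_mm=0)
            assert any(c.n_mismatch_total == 0 for c in cands)

    def test_noncanonical_pam_counts_toward_total(self):
        genome, (pos,) = embed(SPACER + "ATT", seed=5)
        cands = enumerate_candidates(genome, GUIDE, max_total_mm=3)
        hit = [c for c in cands if c.interval.start == pos]
        assert hit and hit[0].n_mismatch_total == 2  # the two non-G PAM bases

    def test_minus_strand_candidate_found(self):
        genome, (pos,) = embed(revcomp(SPACER + "TGG"), seed=7)
        cands = enumerate_candidates(genome, GUIDE, max_total_mm=0)
        assert [(c.interval.start, c.interval.strand) for c in cands if c.n_mismatch_total == 0] == [
            (pos, "-")
        ]

    def test_spacer_length_guard(self):
        with pytest.raises(ValueError):
            enumerate_candidates({"g": "ACGT" * 30}, GuideSpec(spacer="ACGTACGT"), 3)

    def test_rna_spacer_accepted(self):
        g = GuideSpec(spacer=SPACER.replace("T", "U"))
        assert g.spacer == SPACER

    def test_matches_brute_force_scan(self):
        seq = random_genome(30_000, seed=77)
        cands = enumerate_candidates({"g": seq}, GUIDE, max_total_mm=4)
        expected = brute_force_motif_scan(seq, SPACER + "NGG", 4)
        assert sorted(
            (c.interval.start, c.interval.strand, c.n_mismatch_total) for c in cands
        ) == expected

    def test_seed_mismatches_counted_in_pam_proximal_12(self):
        mutated = SPACER[:7] + ("A" if SPACER[7] != "A" else "C") + SPACER[8:]
        distal = mutated[:2]
        genome, (pos,) = embed(mutated + "AGG", seed=9)
        cands = [c for c in enumerate_candidates(genome, GUIDE, 3) if c.interval.start == pos]
        assert cands[0].n_mismatch_total == 1
        assert cands[0].n_mismatch_seed == 0  # position 8 is PAM-distal
        mutated2 = SPACER[:10] + ("A" if SPACER[10] != "A" else "C") + SPACER[11:]
        genome2, (pos2,) = embed(mutated2 + "AGG", seed=10)
        cands2 = [c for c in enumerate_candidates(genome2, GUIDE, 3) if c.interval.start == pos2]
        assert cands2[0].n_mismatch_seed == 1  # position 11 is within the seed


class TestSeedFilterAndGrid:
    def make_cand(self, total, seed_mm, start=0):
        return CandidateSite(
            interval=GenomicInterval("g", start, start + 23, "+"),
            site_seq=SPACER + "AGG",
            n_mismatch_total=total,
            n_mismatch_seed=seed_mm,
            cut_window=GenomicInterval("g", start + 16, start + 18, "."),
        )

    def test_seed_filter_threshold(self):
        cands = [self.make_cand(4, s, start=30 * s) for s in range(5)]
        assert len(seed_filter(cands, 2)) == 3
        assert seed_filter(cands, 5) == cands

    def test_grid_is_32_conditions_and_8_candidate_sets(self):
        conds = standard_conditions()
        assert len(conds) == 32
        assert len({(c.max_total_mm, c.max_seed_mm) for c in conds}) == 8
        assert len(set(conds)) == 32


class TestCallRule:
    COND = FilterCondition(max_total_mm=6, max_seed_mm=5, recurrence_n=5)

    def cand(self, total):
        return CandidateSite(
            interval=GenomicInterval("g", 0, 23, "+"),
            site_seq=SPACER + "AGG",
            n_mismatch_total=total,
            n_mismatch_seed=min(total, 5),
            cut_window=GenomicInterval("g", 16, 18, "."),
        )

    def test_high_mm_singleton_removed(self):
        calls = call_offtargets([self.cand(6)], be_at("g", 16, n=1), self.COND)
        assert calls == []

    def test_high_mm_recurrent_retained(self):
        calls = call_offtargets([self.cand(6)], be_at("g", 16, n=2), self.COND)
        assert len(calls) == 1 and calls[0].n_breaks == 2

    def test_low_mm_singleton_retained(self):
        cond = FilterCondition(6, 5, 2)
        calls = call_offtargets([self.cand(2)], be_at("g", 17, n=1), cond)
        assert len(calls) == 1

    def test_no_breaks_never_called(self):
        assert call_offtargets([self.cand(0)], [], self.COND) == []

    def test_cut_window_overlap_is_strand_blind(self):
        calls = call_offtargets([self.cand(0)], be_at("g", 16, strand="-"), self.COND)
        assert len(calls) == 1

    def test_break_outside_window_not_counted(self):
        assert call_offtargets([self.cand(0)], be_at("g", 18), self.COND) == []


class TestFilterMatrix:
    def setup_method(self):
        rng = np.random.default_rng(31)
        variants = [SPACER + "AGG"]
        spacer = list(SPACER)
        for k, n_mut in enumerate([1, 2, 3, 5, 6]):
            s = spacer.copy()
            for j in range(n_mut):
                i = (3 * k + 5 * j) % 20
                s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
            variants.append("".join(s) + "AGG")
        self.genome, self.positions = embed(*variants, seed=rng.integers(1000))
        self.cands = enumerate_candidates(self.genome, GUIDE, max_total_mm=7)

    def breaks(self, n_per_site=2):
        out = []
        for pos in self.positions:
            out += be_at("g", pos + 17, n=n_per_site)
        return out

    def test_produces_all_32_call_sets(self):
        matrix = run_filter_matrix(self.cands, {"t1": self.breaks()})
        assert len(matrix) == 32

    def test_empty_breakends_give_empty_calls(self):
        matrix = run_filter_matrix(self.cands, {"t1": []})
        assert all(calls == [] for calls in matrix.values())

    def test_monotone_along_each_relaxation_axis(self):
        matrix = run_filter_matrix(self.cands, {"t1": self.breaks(n_per_site=1)})

        def locus_set(cond):
            return {c.candidate.locus for c in matrix[("t1", cond)]}

        for cond in standard_conditions():
            for relaxed in (
                FilterCondition(cond.max_total_mm + 1, cond.max_seed_mm, cond.recurrence_n),
                FilterCondition(cond.max_total_mm, cond.max_seed_mm + 1, cond.recurrence_n),
                FilterCondition(cond.max_total_mm, cond.max_seed_mm, cond.recurrence_n + 1),
            ):
                relaxed_set = {
                    c.candidate.locus
                    for c in run_filter_matrix(
                        self.cands, {"t1": self.breaks(n_per_site=1)}, [relaxed]
                    )[("t1", relaxed)]
                }
                assert locus_set(cond) <= relaxed_set


class TestFdrAndSelection:
    def _matrix(self, t_sites, f_sites):
        """Build a fake call matrix with given treated/control locus counts."""
        cond = FilterCondition(6, 2, 2)
        calls = {}
        for sid, n in (("t1", t_sites), ("c1", f_sites)):
            calls[(sid, cond)] = [
                type("Call", (), {"candidate": type("C", (), {"locus": ("g", i, i + 23, "+")})()})()
                for i in range(n)
            ]
        return calls, cond

    def test_no_control_calls_gives_fdr_zero(self):
        calls, cond = self._matrix(60, 0)
        df = fdr_by_condition(calls, ["t1"], ["c1"])
        assert df.loc[0, "fdr"] == 0.0 and df.loc[0, "n_treated_sites"] == 60

    def test_only_control_calls_gives_fdr_one(self):
        calls, cond = self._matrix(0, 10)
        df = fdr_by_condition(calls, ["t1"], ["c1"])
        assert df.loc[0, "fdr"] == 1.0

    def test_identical_treated_and_control_gives_half(self):
        """With control == treated, F == T > 0, so F/(T+F) = 1/2 everywhere."""
        genome, positions = embed(SPACER + "AGG", seed=2)
        cands = enumerate_candidates(genome, GUIDE, 7)
        breaks = be_at("g", positions[0] + 17, n=3)
        matrix = run_filter_matrix(cands, {"t1": breaks, "c1": breaks})
        df = fdr_by_condition(matrix, ["t1"], ["c1"])
        called = df[df["n_treated_sites"] > 0]
        assert not called.empty and (called["fdr"] == 0.5).all()

    def test_select_max_yield_under_alpha(self):
        df = pd.DataFrame(
            [
                {"max_total_mm": 6, "max_seed_mm": 2, "recurrence_n": 2, "n_treated_sites": 40, "n_control_sites": 0, "fdr": 0.0},
                {"max_total_mm": 7, "max_seed_mm": 4, "recurrence_n": 4, "n_treated_sites": 90, "n_control_sites": 30, "fdr": 0.25},
                {"max_total_mm": 7, "max_seed_mm": 3, "recurrence_n": 3, "n_treated_sites": 60, "n_control_sites": 2, "fdr": 0.032},
            ]
        )
        assert select_condition(df, alpha=0.05) == FilterCondition(7, 3, 3)

    def test_ties_broken_toward_strictest(self):
        rows = [
            {"max_total_mm": t, "max_seed_mm": s, "recurrence_n": r, "n_treated_sites": 50, "n_control_sites": 0, "fdr": 0.0}
            for t in (6, 7)
            for s in (2, 3)
            for r in (2, 3)
        ]
        assert select_condition(pd.DataFrame(rows), alpha=0.05) == FilterCondition(6, 2, 2)

    def test_no_condition_under_alpha_warns_and_returns_min_fdr(self):
        df = pd.DataFrame(
            [
                {"max_total_mm": 6, "max_seed_mm": 2, "recurrence_n": 2, "n_treated_sites": 5, "n_control_sites": 5, "fdr": 0.5},
                {"max_total_mm": 7, "max_seed_mm": 2, "recurrence_n": 2, "n_treated_sites": 9, "n_control_sites": 3, "fdr": 0.25},
            ]
        )
        with pytest.warns(UserWarning):
            assert select_condition(df, alpha=0.01) == FilterCondition(7, 2, 2)


class TestReport:
    def test_mismatch_alignment_marks_only_mismatches(self):
        genome, (pos,) = embed(SPACER + "AGG", seed=4)
        cands = enumerate_candidates(genome, GUIDE, 0)
        text = mismatch_alignment(GUIDE, cands)
        lines = text.splitlines()
        assert lines[1].split()[0] == "." * 23
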