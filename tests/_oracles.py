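"""Independent brute-force oracles used to cross-check the fast scanners.

These deliberately share no code with the package: naive per-window
loops with early exit, numba-compiled when available so whole-genome
sweeps stay cheap in the property suites.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is normally present

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def _codes(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}
    return np.array([table.get(b, 4) for b in seq], dtype=np.int8)


@njit(cache=False)
def _scan(seq: np.ndarray, pat: np.ndarray, max_mm: int):
    n = len(seq) - len(pat) + 1
    starts = []
    mms = []
    for i in range(n):
        mm = 0
        ok = True
        for j in range(len(pat)):
            b = seq[i + j]
            if b == 4 or b == 5:  # non-ACGT genome base never matches
                ok = False
                break
            p = pat[j]
            if p == 5:  # pattern wildcard
                continue
            if b != p:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            starts.append(i)
            mms.append(mm)
    return starts, mms


def brute_force_motif_scan(seq: str, pattern: str, max_mm: int):
    """All (start, strand, mm) windows of ``seq`` within max_mm of pattern.

    Pattern N is a wildcard (for PAMs); genome N never matches. Minus-
    strand hits are windows matching the reverse complement of the
    pattern, reported at their forward-genome coordinates.
    """
    codes = _codes(seq)
    hits = []
    for strand, pat in (("+", pattern), ("-", rc(pattern))):
        starts, mms = _scan(codes, _codes(pat), max_mm)
        hits.extend((int(s), strand, int(m)) for s, m in zip(starts, mms))
    hits.sort()
    return hits


def brute_force_single_linkage(points: list[tuple[float, float]], max_dist: float):
    """Single-linkage clusters of 2-D points by repeated merging (naive)."""
    clusters = [{i} for i in range(len(points))]
    merged = True
    while merged:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(
                    (points[i][0] - points[j][0]) ** 2
                    + (points[i][1] - points[j][1]) ** 2
                    <= max_dist**2
                    for i in clusters[a]
                    for j in clusters[b]
                ):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    return [frozenset(c) for c in clusters]
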