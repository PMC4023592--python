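"""Independent oracles used by the test-suite.

Everything here is written from the problem definition, separately from the
production code paths: a top-down memoized recursion for the frameshift
alignment score, an explicit path enumerator for micro instances, an
alignment re-scorer that walks emitted columns, and a brute-force motif
scanner.
"""

from __future__ import annotations

import sys
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

NEG = float("-inf")

_CODON = dict(unambiguous_dna_by_id[1].forward_table)
for _s in unambiguous_dna_by_id[1].stop_codons:
    _CODON[_s] = "*"


def _tr(codon: str) -> str:
    return _CODON.get(codon, "X")


def _subfn(params):
    mat = substitution_matrices.load(params.matrix_name)
    idx = {c: i for i, c in enumerate(mat.alphabet)}

    def sub(q: str, s: str) -> float:
        if q == "*":
            return float(params.stop_score)
        return float(mat[idx.get(q, idx["X"]), idx.get(s, idx["X"])])

    return sub


def _candidates(dna: str, kind: int, end: int) -> set:
    if kind == 3:
        return {_tr(dna[end - 3 : end])}
    if kind == 4:
        w = dna[end - 4 : end]
        return {_tr(w[:p] + w[p + 1 :]) for p in range(4)}
    w = dna[end - 2 : end]
    return {_tr(w[:p] + b + w[p:]) for p in range(3) for b in "ACGT"}


def oracle_best_score(dna: str, prot: str, params) -> float:
    """Best local frameshift-annotated alignment score on one strand."""
    sub = _subfn(params)
    go, ge, fs = (
        float(params.gap_open),
        float(params.gap_extend),
        float(params.frameshift_penalty),
    )
    n, m = len(dna), len(prot)
    sys.setrecursionlimit(200000)

    @lru_cache(maxsize=None)
    def h(i: int, j: int) -> float:
        best = 0.0
        for k, pen in ((3, 0.0), (2, fs), (4, fs)):
            if i >= k and j >= 1:
                col = max(sub(q, prot[j - 1]) for q in _candidates(dna, k, i))
                best = max(best, h(i - k, j - 1) + col + pen)
        return max(best, e(i, j), f(i, j))

    @lru_cache(maxsize=None)
    def e(i: int, j: int) -> float:
        if j < 1:
            return NEG
        return max(h(i, j - 1) + go, e(i, j - 1) + ge)

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i < 3:
            return NEG
        return max(h(i - 3, j) + go, f(i - 3, j) + ge)

    return max(h(i, j) for i in range(n + 1) for j in range(m + 1))


def enumerate_best_score(dna: str, prot: str, params) -> float:
    """Exhaustive enumeration of every local alignment path (micro only)."""
    sub = _subfn(params)
    go, ge, fs = (
        float(params.gap_open),
        float(params.gap_extend),
        float(params.frameshift_penalty),
    )
    n, m = len(dna), len(prot)
    best = 0.0

    def rec(i: int, j: int, last: str, score: float) -> None:
        nonlocal best
        best = max(best, score)
        for k, pen in ((3, 0.0), (2, fs), (4, fs)):
            if i + k <= n and j + 1 <= m:
                col = max(sub(q, prot[j]) for q in _candidates(dna, k, i + k))
                rec(i + k, j + 1, "M", score + col + pen)
        if j + 1 <= m:
            rec(i, j + 1, "E", score + (ge if last == "E" else go))
        if i + 3 <= n:
            rec(i + 3, j, "F", score + (ge if last == "F" else go))

    for i0 in range(n + 1):
        for j0 in range(m + 1):
            rec(i0, j0, "M", 0.0)
    return best


def rescore_alignment(qstr: str, sstr: str, params) -> float:
    """Recompute an emitted alignment's score column by column."""
    sub = _subfn(params)
    go, ge, fs = (
        float(params.gap_open),
        float(params.gap_extend),
        float(params.frameshift_penalty),
    )
    total = 0.0
    prev = None  # 'E' (gap in query) or 'F' (gap in subject) run tracking
    for q, s in zip(qstr, sstr):
        if q in "/\\":
            total += fs
            # a frameshift column does not interrupt a gap run bookkeeping-
            # wise: it is always adjacent to its own match column
            continue
        if q == "-":
            total += ge if prev == "E" else go
            prev = "E"
        elif s == "-":
            total += ge if prev == "F" else go
            prev = "F"
        else:
            total += sub(q, s)
            prev = None
    return total


def brute_motif(seq: str, spacing=(1, 1, 1)):
    """All-tuples motif search; returns (present, min anchor tuple)."""
    seq = seq.upper()
    n = len(seq)
    s1, s2, s3 = spacing
    tuples = []
    for p1 in range(n):
        if seq[p1] != "D":
            continue
        for p2 in range(p1 + s1 + 1, n):
            if seq[p2] != "D":
                continue
            for p3 in range(p2 + s2 + 1, n):
                if seq[p3] != "D":
                    continue
                for p4 in range(p3 + s3 + 1, n - 4):
                    if (
                        seq[p4] == "Q"
                        and seq[p4 + 3] == "R"
                        and seq[p4 + 4] == "W"
                    ):
                        tuples.append((p1, p2, p3, p4))
    if not tuples:
        return False, None
    return True, min(tuples)
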