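"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's alignment path: the
global-alignment oracle enumerates every monotone alignment of two short
sequences and scores it directly from the scoring definition.
"""

from __future__ import annotations

from functools import lru_cache

from minimito.alignment_identity import ScoringScheme

GAP = "-"


def enumerate_alignments(a: str, b: str):
    """Yield all global alignments as (row_a, row_b) gapped strings."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i == len(a) and j == len(b):
            return [("", "")]
        out = []
        if i < len(a) and j < len(b):
            out += [
                (a[i] + ra, b[j] + rb) for ra, rb in rec(i + 1, j + 1)
            ]
        if i < len(a):
            out += [(a[i] + ra, GAP + rb) for ra, rb in rec(i + 1, j)]
        if j < len(b):
            out += [(GAP + ra, b[j] + rb) for ra, rb in rec(i, j + 1)]
        return out

    return rec(0, 0)


def score_alignment(row_a: str, row_b: str, scheme: ScoringScheme) -> float:
    """Score one alignment straight from the affine-gap definition:
    a gap run of length L costs open + extend * L; terminal runs are
    free when end gaps are free."""
    score = 0.0
    n = len(row_a)
    for x, y in zip(row_a, row_b):
        if x != GAP and y != GAP:
            score += scheme.substitution_score(x, y)

    for row in (row_a, row_b):
        i = 0
        while i < n:
            if row[i] == GAP:
                j = i
                while j < n and row[j] == GAP:
                    j += 1
                terminal = i == 0 or j == n
                if not (scheme.free_end_gaps and terminal):
                    score -= scheme.gap_open + scheme.gap_extend * (j - i)
                i = j
            else:
                i += 1
    return score


def best_score(a: str, b: str, scheme: ScoringScheme) -> float:
    return max(
        score_alignment(ra, rb, scheme)
        for ra, rb in enumerate_alignments(a, b)
    )
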