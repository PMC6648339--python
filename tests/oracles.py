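"""Independent brute-force oracles used to validate the implementation."""

from __future__ import annotations


def enumerate_alignment_score(q: str, r: str, scoring) -> int:
    """Exhaustive-enumeration optimum for the aligner's scoring scheme.

    Recursively explores every monotone alignment path with a 5'-anchored
    start; the path may stop for free once either sequence is exhausted
    (free read 3' overhang / free uncovered reference tail).  A gap of
    length L costs gap_open + L * gap_extend.  Intended for tiny inputs.
    """
    m, n = len(q), len(r)
    ma, mi, o, e = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend

    def rec(i: int, j: int, last: str) -> int:
        options = []
        if i == m or j == n:
            options.append(0)  # stop: the remaining tail is free
        if i < m and j < n:
            s = ma if q[i] == r[j] else mi
            options.append(s + rec(i + 1, j + 1, "M"))
        if j < n:
            cost = e if last == "D" else o + e
            options.append(cost + rec(i, j + 1, "D"))
        if i < m:
            cost = e if last == "I" else o + e
            options.append(cost + rec(i + 1, j, "I"))
        return max(options)

    return rec(0, 0, "M")


def count_dipyrimidine_pairs(seq: str) -> int:
    """Brute-force count of adjacent pyrimidine pairs in a sequence."""
    pyr = set("CT")
    return sum(1 for a, b in zip(seq, seq[1:]) if a in pyr and b in pyr)
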