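"""Global read-to-reference alignment and per-position pileup.

The reference is a fixed short product sequence (73 nt by default), so a
bespoke affine-gap Gotoh aligner is used instead of a general-purpose
mapper.  End rules reflect the assay geometry:

* the read 5' end is anchored at reference position 1 (reads start in the
  sequencing primer); leading gaps are penalised normally;
* the read 3' overhang (adaptor remnant) is free once the reference is
  fully covered;
* reference positions past the end of a read that exhausts itself early
  are free and reported as ``not_covered`` (truncated product).

A gap of length L costs ``gap_open + L * gap_extend``.  All scores are
integers, so traceback decisions are exact.  Indels are left-aligned
within homopolymers after traceback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG = -(10**9)

# call codes
DELETION = "D"
NOT_COVERED = "."


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    min_score: int = 30  # reads scoring below this are rejected as unalignable


@dataclass
class AlignedRead:
    """Per-reference-position calls derived from one alignment."""

    read_id: str
    calls: list[str]  # per reference position: A/C/G/T, 'D' deletion, '.' not covered
    insertions: list[tuple[int, str]] = field(default_factory=list)
    score: int = 0

    @property
    def full_length(self) -> bool:
        return all(c != NOT_COVERED for c in self.calls)

    def call(self, position: int) -> str:
        return self.calls[position - 1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _left_align(qa: list[str], ra: list[str]) -> None:
    """Shift gap runs leftwards within homopolymers, in place.

    A gap run in one row may move one column left whenever the facing base
    it passes equals the facing base at the run's right edge, which keeps
    the score and the implied sequence identical.
    """
    changed = True
    while changed:
        changed = False
        for gapped, other in ((qa, ra), (ra, qa)):
            i = 0
            n = len(gapped)
            while i < n:
                if gapped[i] != "-":
                    i += 1
                    continue
                s = i
                while i < n and gapped[i] == "-":
                    i += 1
                e = i - 1
                if s > 0 and gapped[s - 1] != "-" and other[s - 1] == other[e]:
                    gapped[e] = gapped[s - 1]
                    gapped[s - 1] = "-"
                    changed = True


def _direct_aligned(read_id, q, ref, scoring) -> AlignedRead:
    n = len(ref)
    k = min(len(q), n)
    calls = list(q[:k]) + [NOT_COVERED] * (n - k)
    mm = _hamming(q[:k], ref[:k])
    score = (k - mm) * scoring.match + mm * scoring.mismatch
    return AlignedRead(read_id=read_id, calls=calls, insertions=[], score=score)


def align_read(
    read_bases: str,
    product_reference: str,
    scoring: AlignmentScoring = AlignmentScoring(),
    read_id: str = "",
) -> AlignedRead:
    """Optimally align one read to the product reference.

    Returns the AlignedRead regardless of score; callers apply
    ``scoring.min_score`` to reject unalignable reads.
    """
    q = read_bases.upper()
    ref = product_reference.upper()
    m, n = len(q), len(ref)
    if m == 0 or n == 0:
        return AlignedRead(read_id=read_id, calls=[NOT_COVERED] * n, score=0)

    # fast path: <=1 mismatch in the directly mapped prefix is provably optimal
    # (any alignment containing a gap scores at least gap_open+gap_extend=4 less
    # than a perfect gapless one, and the direct mapping loses only 3 per mismatch)
    k = min(m, n)
    if _hamming(q[:k], ref[:k]) <= 1:
        return _direct_aligned(read_id, q, ref, scoring)

    ma, mi, o, e = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    r_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    jj = np.arange(n + 1, dtype=np.int64)

    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in read (deletion)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in ref (insertion)
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    X[0, 1:] = o + e * jj[1:]
    H[0, 1:] = X[0, 1:]
    for i in range(1, m + 1):
        qi = ord(q[i - 1])
        sub = np.where(r_arr == qi, ma, mi)
        M[i, 1:] = H[i - 1, :-1] + sub
        Y[i, :] = np.maximum(H[i - 1, :] + o + e, Y[i - 1, :] + e)
        # X[i,j] = o + e*j + max_{j'<j} (best non-X state at (i,j') - e*j')
        B = np.maximum(M[i, :], Y[i, :])
        A = B - e * jj
        A[0] = max(A[0], Y[i, 0])
        prefix = np.maximum.accumulate(A)
        X[i, 1:] = o + e * jj[1:] + prefix[:-1]
        H[i, :] = np.maximum(np.maximum(M[i, :], X[i, :]), Y[i, :])

    # endpoint: full reference covered with free read overhang, or read
    # exhausted with a free (not_covered) reference tail
    col = H[:, n]
    row = H[m, :]
    best_i = int(np.argmax(col))
    best_j = int(np.argmax(row))
    if col[best_i] >= row[best_j]:
        i_end, j_end = best_i, n
    else:
        i_end, j_end = m, best_j
    score = int(H[i_end, j_end])

    # traceback (exact integer comparisons)
    i, j = i_end, j_end
    state = "M" if M[i, j] == H[i, j] else ("X" if X[i, j] == H[i, j] else "Y")
    qa: list[str] = []
    ra: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            qa.append("-")
            ra.append(ref[j - 1])
            j -= 1
            continue
        if j == 0:
            qa.append(q[i - 1])
            ra.append("-")
            i -= 1
            continue
        if state == "M":
            qa.append(q[i - 1])
            ra.append(ref[j - 1])
            prev = H[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = "M" if M[i, j] == prev else ("X" if X[i, j] == prev else "Y")
        elif state == "X":
            qa.append("-")
            ra.append(ref[j - 1])
            if X[i, j] == X[i, j - 1] + e:
                j -= 1
                state = "X"
            else:
                target = X[i, j] - o - e
                j -= 1
                state = "M" if M[i, j] == target else "Y"
        else:  # Y
            qa.append(q[i - 1])
            ra.append("-")
            if Y[i, j] == Y[i - 1, j] + e:
                i -= 1
                state = "Y"
            else:
                target = Y[i, j] - o - e
                i -= 1
                state = "M" if M[i, j] == target else "X"
    qa.reverse()
    ra.reverse()
    _left_align(qa, ra)

    calls = [NOT_COVERED] * n
    insertions: list[tuple[int, str]] = []
    ref_pos = 0
    pending_ins: list[str] = []
    for qc, rc in zip(qa, ra):
        if rc == "-":
            pending_ins.append(qc)
            continue
        if pending_ins:
            insertions.append((ref_pos, "".join(pending_ins)))
            pending_ins = []
        ref_pos += 1
        calls[ref_pos - 1] = DELETION if qc == "-" else qc
    if pending_ins:
        insertions.append((ref_pos, "".join(pending_ins)))
    return AlignedRead(read_id=read_id, calls=calls, insertions=insertions, score=score)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, DELETION: 4}
CHANNELS = ("A", "C", "G", "T", "del")


@dataclass
class PositionCounts:
    """Per-reference-position base-call counts over a set of aligned reads."""

    reference: str
    counts: np.ndarray  # (n_positions, 5): A C G T deletion
    insertion_counts: np.ndarray  # anchored at the reference position 5' of the insert
    n_full_length: int
    n_reads: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        n = len(self.reference)
        df = pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "ref_base": list(self.reference),
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "del": self.counts[:, 4],
                "ins": self.insertion_counts[1 : n + 1],
                "depth": self.depth,
            }
        )
        return df


def build_pileup(
    aligned_reads: list[AlignedRead],
    product_reference: str,
    restrict_full_length: bool = True,
) -> PositionCounts:
    """Accumulate per-position counts; by default only full-length reads count."""
    n = len(product_reference)
    counts = np.zeros((n, 5), dtype=np.int64)
    ins = np.zeros(n + 1, dtype=np.int64)
    n_full = 0
    n_used = 0
    for ar in aligned_reads:
        fl = ar.full_length
        if restrict_full_length and not fl:
            continue
        n_used += 1
        if fl:
            n_full += 1
        for pos0, c in enumerate(ar.calls):
            if c == NOT_COVERED:
                continue
            counts[pos0, _BASE_INDEX[c]] += 1
        for anchor, _seq in ar.insertions:
            ins[anchor] += 1
    return PositionCounts(
        reference=product_reference,
        counts=counts,
        insertion_counts=ins,
        n_full_length=n_full,
        n_reads=n_used,
    )
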