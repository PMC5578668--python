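"""Reference-anchored pairwise alignment of amplicon reads.

Each amplicon is aligned on its own to the matching reference window with a
global affine-gap Needleman-Wunsch pass (terminal reference gaps free, so a
slightly short read simply sits inside the window).  Because study sequences
are >98% identical to the reference, per-sample pairwise anchoring replaces
multiple alignment and is fully deterministic.

Insertion events are normalised to their 3'-most (rightmost) equivalent
placement, so an extra base inside a homopolymer or repeat is always reported
after the last reference position it could follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import MISSING, ReferenceSequence
from .sequences import AmpliconSegment, DloopSequence, Insertion

NEG = -1e18


class AlignmentIdentityError(ValueError):
    """Raised when an aligned segment falls below the identity floor."""


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme; a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignedSegment:
    sample_id: str
    region: str
    window: tuple[int, int]
    columns: str  # one character per reference column, '-' for deletion/uncovered
    insertions: tuple[Insertion, ...]
    score: float
    identity: float
    n_mismatch: int


def _fill_matrices(query: str, ref: str, sc: AlignmentScoring, free_end_gaps: bool):
    """Row-vectorised affine DP.  Returns the three (m+1, n+1) score layers."""
    m, n = len(query), len(ref)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in reference = insertion in query
    Y = np.full((m + 1, n + 1), NEG)  # gap in query = deletion
    M[0, 0] = 0.0
    if free_end_gaps:
        Y[0, 1:] = 0.0
    else:
        Y[0, 1:] = sc.gap_open + sc.gap_extend * np.arange(n)
    X[1:, 0] = sc.gap_open + sc.gap_extend * np.arange(m)
    ext = sc.gap_extend
    for i in range(1, m + 1):
        sub = np.where(q[i - 1] == r, sc.match, sc.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, :] = np.maximum(M[i - 1, :] + sc.gap_open, X[i - 1, :] + ext)
        # Y[i, j] = max(M[i, j-1] + open, Y[i, j-1] + ext): prefix-max scan.
        z = M[i, :-1] + sc.gap_open - ext * np.arange(1, n + 1)
        Y[i, 1:] = np.maximum.accumulate(z) + ext * np.arange(1, n + 1)
    return M, X, Y


def _traceback(query, ref, sc, M, X, Y, end_j, state):
    """Recover the operation list ending at (m, end_j) in the given layer."""
    i, j = len(query), end_j
    ops: list[tuple[str, int, int]] = []  # (op, query index, ref index) 1-based
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 and j == 0:
                break
            ops.append(("M", i, j))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            sub = sc.match if query[i - 1] == ref[j - 1] else sc.mismatch
            target = M[i, j] - sub
            state = int(np.argmax(np.abs(np.array(prev) - target) < tol))
            i, j = i - 1, j - 1
        elif state == 1:  # X: query base inserted
            ops.append(("X", i, j))
            if i > 1 and abs(X[i, j] - (X[i - 1, j] + sc.gap_extend)) < tol:
                state = 1
            else:
                state = 0
            i -= 1
        else:  # Y: reference column deleted
            ops.append(("Y", i, j))
            if j > 1 and abs(Y[i, j] - (Y[i, j - 1] + sc.gap_extend)) < tol:
                state = 2
            else:
                state = 0
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0 and state != 2:
            state = 2
        if j == 0 and state != 1:
            state = 1
    ops.reverse()
    return ops


def align_to_window(
    query: str,
    ref_window: str,
    window_start: int,
    scoring: AlignmentScoring | None = None,
    free_end_gaps: bool = True,
) -> tuple[str, tuple[Insertion, ...], float, float, int]:
    """Align ``query`` to a reference window anchored at ``window_start``.

    Returns (columns, insertions, score, identity, n_mismatch).  ``columns``
    has one character per reference column; uncovered or deleted columns are
    '-'.  Insertions are 3'-normalised (after-position, bases) events.
    """
    sc = scoring or AlignmentScoring()
    query = query.upper()
    ref_window = ref_window.upper()
    m, n = len(query), len(ref_window)
    M, X, Y = _fill_matrices(query, ref_window, sc, free_end_gaps)
    if free_end_gaps:
        finals = np.maximum(np.maximum(M[m], X[m]), Y[m])
        end_j = int(len(finals) - 1 - np.argmax(finals[::-1]))  # rightmost max
        score = float(finals[end_j])
    else:
        end_j = n
        score = float(max(M[m, n], X[m, n], Y[m, n]))
    state = int(np.argmax([M[m, end_j], X[m, end_j], Y[m, end_j]]))
    ops = _traceback(query, ref_window, sc, M, X, Y, end_j, state)

    cols = ["-"] * n
    matches = mismatches = aligned = 0
    raw_ins: list[tuple[int, str]] = []  # (ref index after which inserted, base)
    for op, i, j in ops:
        if op == "M":
            cols[j - 1] = query[i - 1]
            aligned += 1
            if query[i - 1] == ref_window[j - 1]:
                matches += 1
            else:
                mismatches += 1
        elif op == "X":
            raw_ins.append((j, query[i - 1]))

    # group consecutive insertions, then rotate each run to its 3'-most spot
    events: list[Insertion] = []
    k = 0
    while k < len(raw_ins):
        j, bases = raw_ins[k][0], raw_ins[k][1]
        k += 1
        while k < len(raw_ins) and raw_ins[k][0] == j:
            bases += raw_ins[k][1]
            k += 1
        while j < n and cols[j] == bases[0] and cols[j] not in MISSING:
            bases = bases[1:] + bases[0]
            j += 1
        events.append((window_start + j - 1, bases))
    identity = matches / aligned if aligned else 0.0
    return "".join(cols), tuple(events), score, identity, mismatches


def align_segment(
    segment: AmpliconSegment,
    reference: ReferenceSequence,
    scoring: AlignmentScoring | None = None,
    min_identity: float = 0.90,
) -> AlignedSegment:
    """Align one amplicon to its nominal reference window.

    Raises :class:`AlignmentIdentityError` when identity falls below
    ``min_identity`` (possible NUMT amplification or contamination).
    """
    start, end = segment.nominal_window
    window = reference.window(start, end)
    nominal = end - start + 1
    if not 0.9 * nominal <= len(segment.bases) <= 1.1 * nominal:
        raise ValueError(
            f"{segment.sample_id}/{segment.region}: segment length "
            f"{len(segment.bases)} outside 10% of nominal {nominal}"
        )
    cols, ins, score, identity, n_mm = align_to_window(
        segment.bases, window, start, scoring
    )
    if identity < min_identity:
        raise AlignmentIdentityError(
            f"{segment.sample_id}/{segment.region}: identity {identity:.3f} "
            f"below floor {min_identity:.2f}; sample excluded"
        )
    return AlignedSegment(
        sample_id=segment.sample_id,
        region=segment.region,
        window=(start, end),
        columns=cols,
        insertions=ins,
        score=score,
        identity=identity,
        n_mismatch=n_mm,
    )
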