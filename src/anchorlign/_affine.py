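"""Affine-gap global alignment core (Gotoh three-state DP).

Used for both residue-level pairwise alignment and profile-profile
alignment during progressive multiple alignment.  The caller supplies a
precomputed substitution score matrix ``S`` (shape len(a) x len(b)); this
module owns the recurrences, the gap model and the canonical traceback.

Gap model: a gap run of length L costs ``gap_open + (L - 1) * gap_extend``;
terminal gaps are charged like internal ones (true end-to-end alignment).
Transitions between the two gap states are allowed (a deletion may directly
follow an insertion, paying a fresh opening), so the DP optimum equals the
optimum over *all* global alignments, which the brute-force enumerations in
the test-suite rely on.

Tie-breaking: on equal scores the traceback prefers diagonal (pairing) over
up (gap in the second sequence) over left (gap in the first), yielding one
canonical optimal alignment.
"""

from __future__ import annotations

import numpy as np

NEG = -1e30  # effectively -inf while staying finite for arithmetic

# traceback op codes
DIAG, UP, LEFT = 0, 1, 2


def affine_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three Gotoh matrices.

    Returns (M, X, Y) with shape (n+1, m+1): M ends in a pairing,
    X in a gap in the second sequence (vertical, consumes a row),
    Y in a gap in the first (horizontal, consumes a column).
    """
    n, m = S.shape
    go, ge = float(gap_open), float(gap_extend)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -go - ge * np.arange(n)
    if m:
        Y[0, 1:] = -go - ge * np.arange(m)

    js = np.arange(m + 1)
    for i in range(1, n + 1):
        # states depending only on the previous row: vectorised
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - go, X[i - 1, 1:] - ge
        )
        X[i, 0] = -go - ge * (i - 1)
        # horizontal state: prefix-max scan over max(M, X) in this row.
        # Y[i,j] = max_{k<j} max(M,X)[i,k] - go - (j-1-k)*ge
        #        = max_{k<j} (max(M,X)[i,k] + k*ge) - go - (j-1)*ge
        mx = np.maximum(M[i], X[i])
        scan = np.maximum.accumulate(mx + ge * js)
        Y[i, 1:] = scan[:-1] - go - ge * (js[1:] - 1)
    return M, X, Y


def _argmax3(vals: tuple[float, float, float]) -> int:
    # preference order encoded by index: 0 beats 1 beats 2 on ties
    best = 0
    for k in (1, 2):
        if vals[k] > vals[best]:
            best = k
    return best


def traceback(M: np.ndarray, X: np.ndarray, Y: np.ndarray,
              gap_open: float, gap_extend: float) -> list[int]:
    """Canonical optimal path as a list of op codes (DIAG/UP/LEFT), 5'->3'."""
    go, ge = float(gap_open), float(gap_extend)
    i, j = M.shape[0] - 1, M.shape[1] - 1
    state = _argmax3((M[i, j], X[i, j], Y[i, j]))
    ops: list[int] = []
    while i > 0 or j > 0:
        if state == 0:  # M: came from a pairing
            ops.append(DIAG)
            prev = _argmax3((M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:  # X: gap in second sequence, consumed row i
            ops.append(UP)
            if i == 1 and j == 0:
                i, state = 0, 0
                continue
            cand = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            state = _argmax3(cand)
            i -= 1
        else:  # Y: gap in first sequence, consumed column j
            ops.append(LEFT)
            if j == 1 and i == 0:
                j, state = 0, 0
                continue
            cand = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            state = _argmax3(cand)
            j -= 1
    ops.reverse()
    return ops


def align_score_path(S: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global score and the canonical optimal path."""
    M, X, Y = affine_dp(S, gap_open, gap_extend)
    score = max(M[-1, -1], X[-1, -1], Y[-1, -1])
    return float(score), traceback(M, X, Y, gap_open, gap_extend)
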