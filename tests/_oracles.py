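"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against the *definitions* (plain DP
recurrences, exhaustive scans), sharing no code with the package's own
alignment or detection paths.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def sw_affine_oracle(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Local affine-gap alignment score by the plain Gotoh recurrence.

    ``gap_open`` is the cost of the first gapped position, ``gap_extend`` of
    each additional one (both positive costs).
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (move along a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def global_affine_oracle(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Global affine-gap alignment score (end gaps penalized), plain Gotoh."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        F[i][0] = -gap_open - (i - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(M[i][j - 1] - gap_open, E[i][j - 1] - gap_extend,
                          F[i][j - 1] - gap_open)
            F[i][j] = max(M[i - 1][j] - gap_open, F[i - 1][j] - gap_extend,
                          E[i - 1][j] - gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            M[i][j] = prev + s
    return max(M[n][m], E[n][m], F[n][m])


def tsd_oracle(s: str, ltr5_start: int, ltr3_end: int,
               lengths=(6, 5, 4)) -> str | None:
    """Longest exact flanking duplication by direct comparison."""
    for L in sorted(lengths, reverse=True):
        if ltr5_start - L < 0 or ltr3_end + L > len(s):
            continue
        up = s[ltr5_start - L:ltr5_start]
        down = s[ltr3_end:ltr3_end + L]
        if "N" not in up and up == down:
            return up
    return None


def seed_oracle(s: str, k: int, dist_min: int, dist_max: int) -> set[tuple[int, int, int]]:
    """All maximal exact repeat runs >= k at distances within the window,
    by scanning every diagonal."""
    x = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    acgt = np.isin(x, np.frombuffer(b"ACGT", dtype=np.uint8))
    out: set[tuple[int, int, int]] = set()
    n = len(s)
    for d in range(dist_min, min(dist_max, n - 1) + 1):
        eq = (x[:-d] == x[d:]) & acgt[:-d] & acgt[d:]
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate([[False], eq, [False]])
        diffs = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diffs == 1)[0]
        ends = np.nonzero(diffs == -1)[0]
        for st, en in zip(starts, ends):
            if en - st >= k:
                out.add((int(st), int(st + d), int(en - st)))
    return out


def repeat_region_oracle(s: str, ltr_min: int, min_identity: float,
                         dist_min: int, dist_max: int) -> list[tuple[int, int, int]]:
    """Direct-repeat regions by exhaustive per-diagonal scan.

    Substitution-only repeats lie on a single diagonal. On every diagonal d
    the maximal-scoring segment under per-position weights +1 (match) / -4
    (mismatch) is found (a segment has positive mean score exactly when its
    identity exceeds 0.8); segments of length >= ltr_min and identity >
    min_identity are reported as (start, diag, length). The detector's
    candidates must correspond 1-1 to these regions up to the alignment band.
    """
    x = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    n = len(s)
    regions = []
    for d in range(dist_min, min(dist_max, n - ltr_min) + 1):
        eq = (x[:-d] == x[d:])
        if len(eq) < ltr_min or not eq.any():
            continue
        w = np.where(eq, 1.0, -4.0)
        S = np.concatenate([[0.0], np.cumsum(w)])
        runmin = np.minimum.accumulate(S[:-1])
        gains = S[1:] - runmin
        end = int(gains.argmax()) + 1
        if gains[end - 1] <= 0:
            continue
        start = int(S[:end].argmin())
        length = end - start
        matches = int(eq[start:end].sum())
        if length >= ltr_min and matches / length > min_identity:
            regions.append((start, int(d), length))
    return regions
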