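"""Vectorized (numpy) engine behind exhaustive censuses and flux scans.

Everything here operates on batches of grid diagrams stored as integer
arrays ``XS``, ``OS`` of shape (B, n) -- row ``b`` is one diagram's pair
of permutations.  Only grid numbers up to 8 are supported (3 bits per
digit in the packed-key encoding, and exhaustive enumeration beyond 8 is
out of reach anyway).

The object API in :mod:`gridknot.grid` / :mod:`gridknot.moves` is the
reference implementation; the batched functions here mirror it
operation-for-operation and are cross-checked against it in the test
suite on exhaustive small-GN scans.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

MAX_BULK_N = 8
_DIGIT_BITS = 3


def perms_array(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1, shape (n!, n)."""
    return np.array(list(permutations(range(n))), dtype=np.int8)


def cycle_inverses(n: int) -> np.ndarray:
    """Inverses of all (n-1)! n-cycles, shape ((n-1)!, n).

    Cycle (0 -> a1 -> a2 -> ... -> a_{n-1} -> 0) for every ordering
    (a1..a_{n-1}) of 1..n-1.  The *inverse* is returned because the
    single-component construction sets os = c^-1 o xs.
    """
    rest = list(permutations(range(1, n)))
    out = np.empty((len(rest), n), dtype=np.int8)
    for k, order in enumerate(rest):
        cyc = [0] * n
        seq = (0,) + order
        for i in range(n):
            cyc[seq[i]] = seq[(i + 1) % n]
        inv = [0] * n
        for i, v in enumerate(cyc):
            inv[v] = i
        out[k] = inv
    return out


# -- packed keys ---------------------------------------------------------


def pack_half(P: np.ndarray) -> np.ndarray:
    """Pack one permutation batch into uint64, most-significant first.

    Numeric order of packed halves equals lexicographic order of rows.
    """
    n = P.shape[1]
    if n > MAX_BULK_N:
        raise ValueError(f"packed keys support n <= {MAX_BULK_N}")
    k = np.zeros(P.shape[0], dtype=np.uint64)
    for c in range(n):
        k = (k << np.uint64(_DIGIT_BITS)) | P[:, c].astype(np.uint64)
    return k


def pack_pair(XS: np.ndarray, OS: np.ndarray) -> np.ndarray:
    n = XS.shape[1]
    return (pack_half(XS) << np.uint64(_DIGIT_BITS * n)) | pack_half(OS)


def unpack_pair(keys: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    B = keys.shape[0]
    XS = np.empty((B, n), dtype=np.int8)
    OS = np.empty((B, n), dtype=np.int8)
    mask = np.uint64((1 << _DIGIT_BITS) - 1)
    k = keys.copy()
    for c in range(n - 1, -1, -1):
        OS[:, c] = (k & mask).astype(np.int8)
        k >>= np.uint64(_DIGIT_BITS)
    for c in range(n - 1, -1, -1):
        XS[:, c] = (k & mask).astype(np.int8)
        k >>= np.uint64(_DIGIT_BITS)
    return XS, OS


def canonical_keys(XS: np.ndarray, OS: np.ndarray) -> np.ndarray:
    """Packed key of the swap-canonical form min((xs,os), (os,xs))."""
    kx = pack_half(XS)
    ko = pack_half(OS)
    n = np.uint64(_DIGIT_BITS * XS.shape[1])
    lo = np.minimum(kx, ko)
    hi = np.maximum(kx, ko)
    return (lo << n) | hi


def invert_perms(P: np.ndarray) -> np.ndarray:
    """Batched permutation inverse."""
    return np.argsort(P, axis=1).astype(np.int8)


# -- winding exponents and determinant fingerprints ---------------------


def winding_batch(XS: np.ndarray, OS: np.ndarray) -> np.ndarray:
    """Winding-number exponent matrices, shape (B, n, n) int8.

    E[b, i, j] = sum over columns c < i of sign_c * [lo_c < j <= hi_c];
    matches :func:`gridknot.invariants.winding_exponents`.
    """
    B, n = XS.shape
    lo = np.minimum(XS, OS)[:, :, None]
    hi = np.maximum(XS, OS)[:, :, None]
    sgn = np.where(OS > XS, 1, -1).astype(np.int8)[:, :, None]
    j = np.arange(n, dtype=np.int8)[None, None, :]
    ind = np.where((j > lo) & (j <= hi), sgn, np.int8(0))
    E = np.zeros((B, n, n), dtype=np.int8)
    np.cumsum(ind[:, :-1, :], axis=1, out=E[:, 1:, :])
    return E


def knot_determinant_batch(E: np.ndarray) -> np.ndarray:
    """|Delta(-1)| for a batch of winding-exponent matrices.

    det of the +-1 matrix (-1)**E divided by 2**(n-1); exact because the
    Hadamard bound at n <= 8 is far below 2**53.
    """
    n = E.shape[1]
    M = np.where(E % 2 == 0, 1.0, -1.0)
    d = np.rint(np.abs(np.linalg.det(M))).astype(np.int64)
    q, r = np.divmod(d, 1 << (n - 1))
    if np.any(r):
        raise ArithmeticError("grid determinant not divisible by 2^(n-1)")
    return q


# -- adjacent-pair geometry and commutation -----------------------------


def col_pair_info(
    XS: np.ndarray,
    OS: np.ndarray,
    XINV: np.ndarray,
    OINV: np.ndarray,
    i: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interleaving and hooked classification of column pair (i, i+1).

    Returns boolean masks ``interleaved`` and ``hooked`` plus the hooked
    rectangle ``area`` (undefined entries arbitrary outside the hooked
    mask).  Mirrors :func:`gridknot.moves.classify_juxtaposition`.
    """
    B = XS.shape[0]
    rows = np.arange(B)
    a1, b1 = XS[:, i], OS[:, i]
    a2, b2 = XS[:, i + 1], OS[:, i + 1]
    lo1, hi1 = np.minimum(a1, b1), np.maximum(a1, b1)
    lo2, hi2 = np.minimum(a2, b2), np.maximum(a2, b2)
    case1 = (lo1 < lo2) & (lo2 < hi1) & (hi1 < hi2)
    case2 = (lo2 < lo1) & (lo1 < hi2) & (hi2 < hi1)
    inter = case1 | case2
    y1 = np.where(case1, hi1, lo1)  # inner endpoint of column i
    y2 = np.where(case1, lo2, hi2)  # inner endpoint of column i+1
    # Row partner of the marking at (i, y1) / (i+1, y2).
    d1 = np.where(a1 == y1, OINV[rows, y1], XINV[rows, y1])
    d2 = np.where(a2 == y2, OINV[rows, y2], XINV[rows, y2])
    hooked = inter & (d1 > i + 1) & (d2 < i)
    area = np.abs(y1.astype(np.int16) - y2.astype(np.int16))
    return inter, hooked, area


def commute_cols(XS: np.ndarray, OS: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    XS2 = XS.copy()
    OS2 = OS.copy()
    XS2[:, [i, i + 1]] = XS[:, [i + 1, i]]
    OS2[:, [i, i + 1]] = OS[:, [i + 1, i]]
    return XS2, OS2


def commute_rows(XS: np.ndarray, OS: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Relabel rows i <-> i+1 in both marking permutations."""

    def relabel(P: np.ndarray) -> np.ndarray:
        Q = P.copy()
        Q[P == i] = i + 1
        Q[P == i + 1] = i
        return Q

    return relabel(XS), relabel(OS)
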