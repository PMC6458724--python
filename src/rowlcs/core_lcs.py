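"""Classical prefix-table LCS: reference implementation and oracles.

The score table ``R`` is the standard (m+1) x (n+1) prefix table with
sentinel row/column 0; sequences are logically 1-based, so ``R[i, j]`` is
the LCS length of ``A[1..i]`` and ``B[1..j]`` and the answer sits at
``R[m, n]``.  ``lcs_length`` keeps only two rows.  ``brute_force_lcs``
is an intentionally exhaustive, independent oracle for tiny inputs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = [
    "lcs_table",
    "lcs_length",
    "brute_force_lcs",
    "traceback",
    "is_subsequence",
    "BRUTE_FORCE_MAX",
]

BRUTE_FORCE_MAX = 15


def lcs_table(a: str, b: str) -> np.ndarray:
    """Full (m+1) x (n+1) prefix score table.

    ``R[i, 0] = R[0, j] = 0``; a match extends the diagonal by one,
    otherwise the cell is the max of the cells above and to the left.
    """
    m, n = len(a), len(b)
    table = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        ai = a[i - 1]
        prev = table[i - 1]
        cur = table[i]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                up = prev[j]
                left = cur[j - 1]
                cur[j] = up if up >= left else left
    return table


def lcs_length(a: str, b: str) -> int:
    """LCS length in O(n) working space (current + previous row only)."""
    if not a or not b:
        return 0
    # iterate over the longer string so the stored rows are the shorter side
    if len(b) > len(a):
        a, b = b, a
    n = len(b)
    prev = [0] * (n + 1)
    cur = [0] * (n + 1)
    for ai in a:
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                up = prev[j]
                left = cur[j - 1]
                cur[j] = up if up >= left else left
        prev, cur = cur, prev
    return prev[n]


def is_subsequence(sub: str, seq: str) -> bool:
    """True if ``sub`` can be obtained from ``seq`` by deleting characters."""
    it = iter(seq)
    return all(ch in it for ch in sub)


def brute_force_lcs(a: str, b: str) -> int:
    """Exhaustive-enumeration oracle; requires ``min(|a|, |b|) <= 15``.

    Enumerates subsequences of the shorter string by descending length and
    returns the length of the first one that is also a subsequence of the
    longer string.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) > BRUTE_FORCE_MAX:
        raise ValueError(
            f"brute_force_lcs requires min length <= {BRUTE_FORCE_MAX}, "
            f"got {len(short)}"
        )
    for length in range(len(short), 0, -1):
        seen = set()
        for idx in combinations(range(len(short)), length):
            cand = "".join(short[i] for i in idx)
            if cand in seen:
                continue
            seen.add(cand)
            if is_subsequence(cand, long_):
                return length
    return 0


def traceback(table: np.ndarray, a: str, b: str) -> str:
    """Recover one LCS string from a table produced by :func:`lcs_table`.

    Tie rule: prefer the diagonal move on a match, else move up
    (decrement i), else left.  Deterministic by construction.
    """
    m, n = len(a), len(b)
    if table.shape != (m + 1, n + 1):
        raise ValueError(
            f"table shape {table.shape} does not match sequences "
            f"({m + 1}, {n + 1})"
        )
    out: list[str] = []
    i, j = m, n
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1] and table[i, j] == table[i - 1, j - 1] + 1:
            out.append(a[i - 1])
            i -= 1
            j -= 1
        elif table[i - 1, j] == table[i, j]:
            i -= 1
        else:
            j -= 1
    return "".join(reversed(out))
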