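"""Row-wise-independent LCS kernels with occurrence-table preprocessing.

Every cell of score row ``i`` can be written from row ``i - 1`` alone once
the last-occurrence positions of each alphabet character in ``B`` have been
tabulated.  Let ``occ(c, j)`` be the largest 1-based position ``p <= j``
with ``B[p] == C[c]`` (0 if none).  Two table variants are kept:

* ``v2_direct`` stores ``occ(c, j)`` itself; the row kernel then needs only
  two data branches and never compares sequence characters.
* ``v1_offset`` stores ``occ(c, j) - 1`` (sentinel -1 for "no occurrence");
  its row kernel keeps the explicit character-match branch, three data
  branches in total.

Both kernels reproduce the classical prefix recurrence row for row:
when ``occ(c, j) = p > 0``, ``R[i, j] = max(R[i-1, j], R[i-1, p-1] + 1)``,
and ``R[i, j] = R[i-1, j]`` when the character does not occur in
``B[1..j]``.  Because each output element reads only the previous row and
the precomputed table, the elements of a row may be evaluated in any
order — sequentially, chunked, or concurrently — with identical results;
:class:`ExecutionPolicy` configures how the column range is shared.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .seqio import Alphabet, build_alphabet

__all__ = [
    "OccurrenceTable",
    "ExecutionPolicy",
    "SCHEDULES",
    "build_occurrence_table",
    "row_update_v1",
    "row_update_v2",
    "lcs_length_rowwise",
    "partition",
]

SCHEDULES = ("static", "dynamic", "guided")
VARIANTS = ("v1_offset", "v2_direct")

# below this column count the thread pool costs more than it saves
_PARALLEL_MIN_N = 8192
# average chunk length below which a pure-Python row loop beats numpy slicing
_SMALL_CHUNK = 32


def _default_workers() -> int:
    return min(os.cpu_count() or 1, 16)


@dataclass(frozen=True)
class ExecutionPolicy:
    """Work-sharing configuration for one row of columns.

    ``chunk="auto"`` means ceil(n / workers) for the static schedule and
    1 for dynamic/guided (the guided floor).
    """

    workers: int = field(default_factory=_default_workers)
    schedule: str = "static"
    chunk: int | str = "auto"

    def __post_init__(self):
        if not isinstance(self.workers, int) or self.workers < 1:
            raise ValueError(f"workers must be a positive integer, got {self.workers!r}")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"schedule must be one of {SCHEDULES}, got {self.schedule!r}")
        if self.chunk != "auto" and (not isinstance(self.chunk, int) or self.chunk < 1):
            raise ValueError(f"chunk must be 'auto' or a positive integer, got {self.chunk!r}")


@dataclass(frozen=True)
class OccurrenceTable:
    """Last-occurrence table P over ``|C|`` rows and ``n + 1`` columns."""

    variant: str
    alphabet: Alphabet
    values: np.ndarray  # shape (|C|, n + 1), row c-1 for rank c

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    def row(self, c: int) -> np.ndarray:
        """Row for alphabet rank ``c`` (1-based)."""
        if not 1 <= c <= len(self.alphabet):
            raise ValueError(f"rank {c} out of range 1..{len(self.alphabet)}")
        return self.values[c - 1]


def build_occurrence_table(b: str, alphabet: Alphabet,
                           variant: str = "v2_direct") -> OccurrenceTable:
    """Tabulate last occurrences of every alphabet character in ``b``.

    Rows are mutually independent; the result is identical however they
    are computed.  Every character of ``b`` must have a rank.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    missing = set(b) - set(alphabet.symbols)
    if missing:
        raise ValueError(f"characters of B absent from alphabet: {sorted(missing)!r}")
    n = len(b)
    values = np.zeros((len(alphabet), n + 1), dtype=np.int64)
    if n:
        b_codes = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
        positions = np.arange(1, n + 1, dtype=np.int64)
        for c, ch in enumerate(alphabet.symbols, start=1):
            hits = np.where(b_codes == ord(ch), positions, 0)
            np.maximum.accumulate(hits, out=values[c - 1, 1:])
    if variant == "v1_offset":
        values -= 1  # occ - 1, so "no occurrence" becomes the -1 sentinel
    return OccurrenceTable(variant=variant, alphabet=alphabet, values=values)


# ---------------------------------------------------------------------------
# row kernels (vectorized over a 1-based column slice [lo, hi])

def _v1_slice(prev, out, args, lo, hi):
    a_code, b_codes, off_row = args
    sl = slice(lo, hi + 1)
    off = off_row[sl]
    match = b_codes[lo - 1:hi] == a_code
    cur = prev[sl]
    ext = prev[off] + 1  # off == -1 wraps but is masked by the off < 0 branch
    out[sl] = np.where(match, prev[lo - 1:hi] + 1,
                       np.where(off < 0, cur, np.maximum(cur, ext)))


def _v2_slice(prev, out, occ_row, lo, hi):
    sl = slice(lo, hi + 1)
    occ = occ_row[sl]
    cand = np.where(occ > 0, prev[occ - 1] + 1, 0)  # occ == 0 masked likewise
    out[sl] = np.maximum(prev[sl], cand)


def row_update_v1(prev, i: int, a: str, b: str, alphabet: Alphabet,
                  table: OccurrenceTable) -> np.ndarray:
    """Score row ``i`` from row ``i - 1`` using the three-branch kernel.

    Branches: character match (diagonal + 1), occurrence found
    (max of carry-down and extension), no occurrence (carry down).
    """
    if table.variant != "v1_offset":
        raise ValueError(f"row_update_v1 needs a v1_offset table, got {table.variant}")
    n = len(b)
    prev = np.asarray(prev, dtype=np.int64)
    if prev.shape != (n + 1,):
        raise ValueError(f"prev row has length {prev.shape[0]}, expected {n + 1}")
    if not 1 <= i <= len(a):
        raise ValueError(f"row index {i} out of range 1..{len(a)}")
    c = alphabet.rank[a[i - 1]]
    out = np.zeros(n + 1, dtype=np.int64)
    if n:
        b_codes = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
        _v1_slice(prev, out, (ord(a[i - 1]), b_codes, table.row(c)), 1, n)
    return out


def row_update_v2(prev, c: int, table: OccurrenceTable,
                  n: int | None = None) -> np.ndarray:
    """Score row from the previous row using only the rank ``c`` and P.

    Two data branches, no sequence-character comparison: carry down when
    ``P[c, j] = 0``, else ``max(prev[j], prev[P[c, j] - 1] + 1)``.
    """
    if table.variant != "v2_direct":
        raise ValueError(f"row_update_v2 needs a v2_direct table, got {table.variant}")
    if n is None:
        n = table.cols - 1
    prev = np.asarray(prev, dtype=np.int64)
    if prev.shape != (n + 1,):
        raise ValueError(f"prev row has length {prev.shape[0]}, expected {n + 1}")
    occ_row = table.row(c)  # validates c
    out = np.zeros(n + 1, dtype=np.int64)
    if n:
        _v2_slice(prev, out, occ_row, 1, n)
    return out


# ---------------------------------------------------------------------------
# work sharing

def partition(n: int, policy: ExecutionPolicy) -> list[tuple[int, int]]:
    """Split columns ``[1..n]`` into the policy's chunk ranges (inclusive).

    static/dynamic: fixed-size chunks (auto = ceil(n/workers) resp. 1);
    guided: chunk sizes proportional to remaining work, floored at the
    configured chunk.  Ranges are disjoint, ascending, and cover [1..n].
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return []
    if policy.schedule == "guided":
        floor = policy.chunk if policy.chunk != "auto" else 1
        ranges = []
        lo = 1
        while lo <= n:
            size = max(floor, ceil((n - lo + 1) / policy.workers))
            hi = min(lo + size - 1, n)
            ranges.append((lo, hi))
            lo = hi + 1
        return ranges
    if policy.chunk == "auto":
        size = ceil(n / policy.workers) if policy.schedule == "static" else 1
    else:
        size = policy.chunk
    return [(lo, min(lo + size - 1, n)) for lo in range(1, n + 1, size)]


def _drain(kernel, prev, out, args, chunk_iter):
    # next() on a shared list iterator is atomic under the GIL, giving
    # next-free-worker claiming for the dynamic and guided schedules
    for lo, hi in chunk_iter:
        kernel(prev, out, args, lo, hi)


def _run_chunks(kernel, prev, out, args, chunks):
    for lo, hi in chunks:
        kernel(prev, out, args, lo, hi)


def lcs_length_rowwise(a: str, b: str, version: str = "v2",
                       policy: ExecutionPolicy | None = None) -> int:
    """LCS length via the row-wise-independent kernels, two rows of storage.

    The result is a pure function of ``(a, b)``: identical for both kernel
    versions and for every worker count, schedule, and chunk size.
    """
    if version not in ("v1", "v2"):
        raise ValueError(f"version must be 'v1' or 'v2', got {version!r}")
    if policy is None:
        policy = ExecutionPolicy()
    elif not isinstance(policy, ExecutionPolicy):
        raise ValueError(f"policy must be an ExecutionPolicy, got {type(policy).__name__}")
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return 0
    alphabet = build_alphabet(a, b)
    variant = "v1_offset" if version == "v1" else "v2_direct"
    table = build_occurrence_table(b, alphabet, variant)
    chunks = partition(n, policy)

    if n // len(chunks) < _SMALL_CHUNK and n <= _PARALLEL_MIN_N:
        return _run_small(a, b, alphabet, table, version, chunks)

    if version == "v1":
        kernel = _v1_slice
        b_codes = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)

        def row_args(i):
            c = alphabet.rank[a[i - 1]]
            return ord(a[i - 1]), b_codes, table.row(c)
    else:
        kernel = _v2_slice

        def row_args(i):
            return table.row(alphabet.rank[a[i - 1]])

    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.zeros(n + 1, dtype=np.int64)
    threaded = policy.workers > 1 and n >= _PARALLEL_MIN_N and len(chunks) > 1
    pool = ThreadPoolExecutor(policy.workers) if threaded else None
    static_groups = None
    if threaded and policy.schedule == "static":
        static_groups = [g for w in range(policy.workers)
                         if (g := chunks[w::policy.workers])]
    try:
        for i in range(1, m + 1):
            args = row_args(i)
            cur[0] = 0
            if pool is None:
                _run_chunks(kernel, prev, cur, args, chunks)
            elif static_groups is not None:
                futures = [pool.submit(_run_chunks, kernel, prev, cur, args, g)
                           for g in static_groups]
                for f in futures:
                    f.result()
            else:
                chunk_iter = iter(chunks)
                futures = [pool.submit(_drain, kernel, prev, cur, args, chunk_iter)
                           for _ in range(policy.workers)]
                for f in futures:
                    f.result()
            prev, cur = cur, prev
        return int(prev[n])
    finally:
        if pool is not None:
            pool.shutdown()


def _run_small(a, b, alphabet, table, version, chunks):
    # plain-list row loop: avoids per-chunk numpy overhead when chunks are tiny
    n = len(b)
    rows = [r.tolist() for r in table.values]
    prev = [0] * (n + 1)
    cur = [0] * (n + 1)
    for ai in a:
        p_row = rows[alphabet.rank[ai] - 1]
        if version == "v2":
            for lo, hi in chunks:
                for j in range(lo, hi + 1):
                    occ = p_row[j]
                    keep = prev[j]
                    if occ:
                        ext = prev[occ - 1] + 1
                        cur[j] = ext if ext > keep else keep
                    else:
                        cur[j] = keep
        else:
            for lo, hi in chunks:
                for j in range(lo, hi + 1):
                    if ai == b[j - 1]:
                        cur[j] = prev[j - 1] + 1
                    else:
                        off = p_row[j]
                        keep = prev[j]
                        if off < 0:
                            cur[j] = keep
                        else:
                            ext = prev[off] + 1
                            cur[j] = ext if ext > keep else keep
        prev, cur = cur, prev
    return prev[n]
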