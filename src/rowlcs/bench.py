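"""Timing harness for the LCS implementations.

Reproduces the shape of the tuning/comparison experiments (algorithms x
execution policies, repeated timings, relative and absolute speedups).
Wall-clock numbers are machine-dependent; the harness cross-validates the
computed LCS length across all configurations as it measures.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from . import core_lcs, rowpar
from .rowpar import ExecutionPolicy

__all__ = [
    "BenchmarkRecord",
    "ALGORITHMS",
    "SEQUENTIAL_ALGORITHMS",
    "run_benchmark",
    "compute_speedups",
    "write_report",
]

SEQUENTIAL_ALGORITHMS = ("classic_full", "classic_tworow")
PARALLEL_ALGORITHMS = ("v1", "v2")
ALGORITHMS = SEQUENTIAL_ALGORITHMS + PARALLEL_ALGORITHMS

REPORT_COLUMNS = [
    "algorithm", "workers", "schedule", "chunk", "length_a", "length_b",
    "repeats", "min_time", "mean_time", "result_length",
    "relative_speedup", "absolute_speedup",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    algorithm: str
    policy: ExecutionPolicy
    length_a: int
    length_b: int
    repeats: int
    wall_times: tuple[float, ...]
    result_length: int

    @property
    def min_time(self) -> float:
        return min(self.wall_times)

    @property
    def mean_time(self) -> float:
        return sum(self.wall_times) / len(self.wall_times)


def _residues(seq) -> str:
    return seq.residues if hasattr(seq, "residues") else str(seq)


def _run_once(algorithm: str, a: str, b: str, policy: ExecutionPolicy):
    # timed region: alphabet + occurrence-table construction + score loop
    start = time.perf_counter()
    if algorithm == "classic_full":
        result = int(core_lcs.lcs_table(a, b)[-1, -1])
    elif algorithm == "classic_tworow":
        result = core_lcs.lcs_length(a, b)
    else:
        result = rowpar.lcs_length_rowwise(a, b, version=algorithm, policy=policy)
    return time.perf_counter() - start, result


def run_benchmark(pair, algorithms, policies, repeats: int = 3):
    """One :class:`BenchmarkRecord` per (algorithm, policy) combination."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for name in algorithms:
        if name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
    a, b = (_residues(s) for s in pair)
    records = []
    for algorithm in algorithms:
        for policy in policies:
            times = []
            result = None
            for _ in range(repeats):
                elapsed, result = _run_once(algorithm, a, b, policy)
                times.append(elapsed)
            records.append(BenchmarkRecord(
                algorithm=algorithm, policy=policy,
                length_a=len(a), length_b=len(b),
                repeats=repeats, wall_times=tuple(times),
                result_length=result,
            ))
    return records


def compute_speedups(records):
    """Relative and absolute speedups per record (None when undefined).

    relative = best 1-worker time of the same algorithm / record's best time;
    absolute = best time over the sequential algorithms / record's best time.
    """
    sequential = [r.min_time for r in records
                  if r.algorithm in SEQUENTIAL_ALGORITHMS]
    best_sequential = min(sequential) if sequential else None
    baseline: dict[str, float] = {}
    for r in records:
        if r.policy.workers == 1:
            cur = baseline.get(r.algorithm)
            baseline[r.algorithm] = r.min_time if cur is None else min(cur, r.min_time)
    report = []
    for r in records:
        base = baseline.get(r.algorithm)
        report.append({
            "algorithm": r.algorithm,
            "workers": r.policy.workers,
            "schedule": r.policy.schedule,
            "chunk": r.policy.chunk,
            "length_a": r.length_a,
            "length_b": r.length_b,
            "repeats": r.repeats,
            "min_time": r.min_time,
            "mean_time": r.mean_time,
            "result_length": r.result_length,
            "relative_speedup": None if base is None else base / r.min_time,
            "absolute_speedup": (None if best_sequential is None
                                 else best_sequential / r.min_time),
        })
    return report


def write_report(records, speedups, path) -> pd.DataFrame:
    """Write one CSV row per record (stable column order); returns the frame."""
    frame = pd.DataFrame(speedups, columns=REPORT_COLUMNS)
    frame.to_csv(path, index=False)
    return frame
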