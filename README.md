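# rowlcs

Row-wise parallel **longest common subsequence** (LCS) length computation for
DNA (or arbitrary-alphabet) sequence pairs.

The classical LCS prefix-table recurrence makes each cell depend on its left
neighbour in the same row. `rowlcs` implements the row-wise-independent
reformulation: a per-character *last-occurrence table* `P` over the second
sequence removes the in-row dependency, so every cell of a score row can be
computed from the previous row alone — in any order, chunked, or concurrently.
Two kernel variants are provided:

- **v1** — `P` stores `occ(c, j) - 1` (sentinel `-1`); the row kernel keeps an
  explicit character-match branch (three data branches).
- **v2** — `P` stores `occ(c, j)` directly; the row kernel needs only two
  branches and never compares sequence characters.

Both reproduce the classical recurrence exactly and run with two-row storage
(`O(n)` working memory plus the `|C| x (n+1)` table `P`). Work sharing across
a row is configurable (`workers`, `static`/`dynamic`/`guided` schedule, chunk
size); the result is invariant to the policy by construction.

## Modules

| Module | Contents |
| --- | --- |
| `rowlcs.seqio` | FASTA reading/writing, sanitization, joint-alphabet construction |
| `rowlcs.core_lcs` | classical full-table and two-row LCS, brute-force oracle, traceback |
| `rowlcs.rowpar` | occurrence tables, v1/v2 row kernels, work-sharing driver |
| `rowlcs.synth` | seeded uniform DNA generator, planted-subsequence pair generator |
| `rowlcs.bench` | timing harness, relative/absolute speedups, CSV report |
| `rowlcs.cli` | `rowlcs` command-line entry point |

## CLI

```bash
# LCS length of the first records of two FASTA files
rowlcs length --a A.fa --b B.fa --algo v2 --workers 4 --schedule static --chunk auto

# deterministic random DNA
rowlcs gen --length 32768 --seed 1 --out A.fa

# timing report (synthetic pair, CSV output)
rowlcs bench --length-a 8192 --seed 1 --algos classic_tworow,v1,v2 \
    --workers 1,2,4 --schedules static,dynamic --repeats 3 --out report.csv

# seeded cross-implementation consistency check
rowlcs selftest --trials 500 --seed 0
```

`length` prints the bare decimal length on stdout (diagnostics go to stderr);
exit status is 0 on success, 1 on validation/format errors, 2 on usage errors.

## API sketch

```python
from rowlcs import lcs_length, lcs_length_rowwise, ExecutionPolicy

lcs_length("AGCAT", "GAC")                      # 2, classical two-row
policy = ExecutionPolicy(workers=4, schedule="static", chunk="auto")
lcs_length_rowwise("AGCAT", "GAC", "v2", policy)  # 2, row-wise kernel
```

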