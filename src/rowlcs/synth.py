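"""Seeded synthetic DNA generators.

Uniform random sequences (lengths in the spirit of 128..32768 bp) and
pairs with a planted common subsequence giving a provable LCS lower
bound.  All randomness comes from numpy's PCG64 so identical parameters
reproduce identical output across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SequenceRecord

__all__ = ["SyntheticPairSpec", "generate_dna", "generate_planted_pair"]

DEFAULT_ALPHABET = "ACGT"


@dataclass(frozen=True)
class SyntheticPairSpec:
    length_a: int
    length_b: int
    seed: int
    plant_length: int = 0
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self):
        if self.length_a < 0 or self.length_b < 0:
            raise ValueError("sequence lengths must be nonnegative")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if not 0 <= self.plant_length <= min(self.length_a, self.length_b):
            raise ValueError(
                f"plant_length {self.plant_length} exceeds "
                f"min(length_a, length_b) = {min(self.length_a, self.length_b)}"
            )


def _random_string(rng: np.random.Generator, length: int, alphabet: str) -> str:
    if length == 0:
        return ""
    symbols = np.array(list(alphabet))
    return "".join(symbols[rng.integers(0, len(alphabet), size=length)])


def generate_dna(length: int, seed: int,
                 alphabet: str = DEFAULT_ALPHABET) -> SequenceRecord:
    """Uniform i.i.d. sequence of ``length`` residues, deterministic in seed."""
    if length < 0:
        raise ValueError("length must be nonnegative")
    if length > 0 and not alphabet:
        raise ValueError("alphabet must be non-empty for length > 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    return SequenceRecord(
        id=f"synth_len{length}_seed{seed}",
        residues=_random_string(rng, length, alphabet),
        description=f"uniform random, alphabet={alphabet}",
    )


def generate_planted_pair(spec: SyntheticPairSpec):
    """Pair of random sequences sharing a planted common subsequence.

    A random string of ``plant_length`` residues is embedded in order (at
    sorted random positions, not necessarily contiguous) in both outputs,
    so ``LCS(A, B) >= plant_length``.  Returns ``(rec_a, rec_b, bound)``.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    plant = _random_string(rng, spec.plant_length, spec.alphabet)

    def build(length: int, tag: str) -> SequenceRecord:
        residues = list(_random_string(rng, length, spec.alphabet))
        if spec.plant_length:
            positions = np.sort(
                rng.choice(length, size=spec.plant_length, replace=False)
            )
            for pos, ch in zip(positions, plant):
                residues[pos] = ch
        return SequenceRecord(
            id=f"planted_{tag}_len{length}_seed{spec.seed}",
            residues="".join(residues),
            description=f"planted common subsequence length {spec.plant_length}",
        )

    return build(spec.length_a, "a"), build(spec.length_b, "b"), spec.plant_length
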