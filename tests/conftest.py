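"""Shared fixtures: deterministic synthetic sequences and arrays."""

import random

import pytest


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng: random.Random, seq: str, p: float) -> str:
    return "".join(
        rng.choice([b for b in "ACGT" if b != c]) if rng.random() < p else c
        for c in seq
    )


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def repeat_array_fixture(rng):
    """IGS-like sequence with a dissectable array: N1 + A B A B B C C + N2.

    The adjacent same-type copies (B B, C C) make every unit boundary
    recoverable from self-similarity.  Returns (sequence, truth units).
    """
    A, B, C = random_dna(rng, 200), random_dna(rng, 130), random_dna(rng, 90)
    units = {"A": A, "B": B, "C": C}
    order = ["A", "B", "A", "B", "B", "C", "C"]
    n1, n2 = random_dna(rng, 300), random_dna(rng, 400)
    parts, truth, pos = [], [], len(n1)
    for t in order:
        s = mutate(rng, units[t], 0.02)
        parts.append(s)
        truth.append((t, pos, pos + len(s)))
        pos += len(s)
    return n1 + "".join(parts) + n2, truth
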