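"""Exhaustive enumeration of nested secondary structures.

A reference implementation used to validate the dynamic-programming engine on
short sequences: it enumerates every valid nested structure by recursion on
the first position (unpaired, or paired to each admissible partner), computes
Boltzmann weights term by term, and derives the MFE, the partition function
and exact pair frequencies by direct summation.  It deliberately shares no
code with :mod:`sdckit.fold`.
"""

from __future__ import annotations

import math
from itertools import combinations

from .fold import DEFAULT_PAIR_ENERGIES, RnaSequence, SecondaryStructure

__all__ = [
    "enumerate_structures",
    "structure_energy",
    "brute_force_mfe",
    "brute_force_partition",
    "brute_force_pair_probabilities",
    "brute_force_structure_probabilities",
]


def _pairable(a: str, b: str, energies) -> bool:
    return (a, b) in energies


def enumerate_structures(
    seq: RnaSequence, min_loop: int = 3, pair_energies=None
) -> list[SecondaryStructure]:
    """All valid nested structures of ``seq`` (feasible for n up to ~16)."""
    energies = DEFAULT_PAIR_ENERGIES if pair_energies is None else pair_energies
    res = seq.residues
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        if i >= j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [frozenset(s) for s in rec(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if _pairable(res[i], res[k], energies):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(left | right | {(i + 1, k + 1)})
        memo[key] = out
        return out

    return [SecondaryStructure(n=seq.n, pairs=p) for p in rec(0, seq.n - 1)]


def structure_energy(seq: RnaSequence, s: SecondaryStructure, pair_energies=None) -> float:
    energies = DEFAULT_PAIR_ENERGIES if pair_energies is None else pair_energies
    res = seq.residues
    return sum(energies[(res[i - 1], res[j - 1])] for i, j in s.pairs)


def brute_force_mfe(
    seq: RnaSequence, min_loop: int = 3, pair_energies=None
) -> tuple[float, SecondaryStructure]:
    """Minimum energy and its structure; ties broken by sorted pair list."""
    structures = enumerate_structures(seq, min_loop, pair_energies)
    scored = [(structure_energy(seq, s, pair_energies), s.sorted_pairs, s) for s in structures]
    e_min = min(e for e, _, _ in scored)
    best = min((pl, s) for e, pl, s in scored if e == e_min)
    return e_min, best[1]


def brute_force_partition(
    seq: RnaSequence, kT: float = 1.0, min_loop: int = 3, pair_energies=None
) -> float:
    return sum(
        math.exp(-structure_energy(seq, s, pair_energies) / kT)
        for s in enumerate_structures(seq, min_loop, pair_energies)
    )


def brute_force_structure_probabilities(
    seq: RnaSequence, kT: float = 1.0, min_loop: int = 3, pair_energies=None
) -> dict[frozenset, float]:
    """Boltzmann probability of every structure, keyed by its pair set."""
    structures = enumerate_structures(seq, min_loop, pair_energies)
    weights = [
        math.exp(-structure_energy(seq, s, pair_energies) / kT) for s in structures
    ]
    z = sum(weights)
    return {s.pairs: w / z for s, w in zip(structures, weights)}


def brute_force_pair_probabilities(
    seq: RnaSequence, kT: float = 1.0, min_loop: int = 3, pair_energies=None
):
    """Exact pair-probability matrix by weighted counting over all structures."""
    import numpy as np

    probs = brute_force_structure_probabilities(seq, kT, min_loop, pair_energies)
    p = np.zeros((seq.n, seq.n))
    for pairs, w in probs.items():
        for i, j in pairs:
            p[i - 1, j - 1] += w
            p[j - 1, i - 1] += w
    return p
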