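"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import pytest

from ssea_omp import (
    Element,
    ElementSequence,
    LibraryEntry,
    ReferenceLibrary,
    ScoringScheme,
    SSEType,
    element_score,
)

STATES = "HEC"


def random_sse_string(rng: np.random.Generator, length: int) -> str:
    return "".join(STATES[i] for i in rng.integers(0, 3, size=length))


def random_element_sequence(
    rng: np.random.Generator, n_elements: int, max_len: int = 10, id: str = "rand"
) -> ElementSequence:
    """Random element sequence with adjacent types guaranteed distinct."""
    types: List[str] = []
    prev = None
    for _ in range(n_elements):
        choices = [s for s in STATES if s != prev]
        prev = choices[int(rng.integers(len(choices)))]
        types.append(prev)
    return ElementSequence(
        id,
        tuple(
            Element(SSEType(t), int(rng.integers(1, max_len + 1))) for t in types
        ),
    )


def brute_force_total_score(
    a: ElementSequence, b: ElementSequence, scheme: ScoringScheme
) -> float:
    """Exhaustive maximum over all monotone element matchings.

    Independent of the DP: for every k, every k-subset of A's indices is
    paired in order with every k-subset of B's indices; unmatched
    elements each pay the gap cost.  Exponential — only for tiny inputs.
    """
    m, n = len(a), len(b)
    best = -scheme.gap_cost * (m + n)  # empty matching
    for k in range(1, min(m, n) + 1):
        for ia in combinations(range(m), k):
            for ib in combinations(range(n), k):
                s = sum(
                    element_score(a.elements[i], b.elements[j], scheme)
                    for i, j in zip(ia, ib)
                )
                s -= scheme.gap_cost * (m + n - 2 * k)
                best = max(best, s)
    return best


@pytest.fixture
def toy_library() -> ReferenceLibrary:
    """2 OMP-like + 2 non-OMP entries, separable by construction."""
    from ssea_omp import compress

    barrel1 = "CC" + "EEEEEEEECCC" * 10 + "CC"
    barrel2 = "CCC" + "EEEEEEECCCC" * 9 + "C"
    helix1 = "CC" + "HHHHHHHHHHHHCCCC" * 5 + "CC"
    helix2 = "CCC" + "HHHHHHHHHHCCCCC" * 6 + "C"
    return ReferenceLibrary(
        [
            LibraryEntry("omp1", "OMP", compress(barrel1, id="omp1")),
            LibraryEntry("omp2", "OMP", compress(barrel2, id="omp2")),
            LibraryEntry("non1", "non-OMP", compress(helix1, id="non1")),
            LibraryEntry("non2", "non-OMP", compress(helix2, id="non2")),
        ]
    )
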