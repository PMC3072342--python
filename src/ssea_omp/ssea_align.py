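"""Secondary structure element alignment (SSEA) by dynamic programming.

Two element sequences are aligned globally over *elements* (never split):
the score for pairing elements a and b is

    S(a, b) = w(type_a, type_b) * min(L_a, L_b)

with symmetric weights w in [0, 1] (default: 1 on the diagonal, 0 across
types) and a gap cost of 0 residues.  With zero gap cost the optimal
alignment is the maximum-weight monotone (crossing-free) matching of
elements, computed by the Needleman-Wunsch-style recurrence

    F(i, j) = max(F(i-1, j), F(i, j-1), F(i-1, j-1) + S(i, j)).

Because S(a, b) <= min(L_a, L_b), the total score never exceeds the
smaller residue length; dividing by the mean residue length of the two
proteins yields the normalized similarity

    SSEA_Score = total_score / ((L_A + L_B) / 2)   in [0, 1],

with 1 attained exactly by self-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .sse_model import Element, ElementSequence, SSEType

TypePair = FrozenSet[SSEType]


def _pair(a: SSEType, b: SSEType) -> TypePair:
    return frozenset((a, b))


_DEFAULT_WEIGHTS: Dict[TypePair, float] = {
    _pair(SSEType.H, SSEType.H): 1.0,
    _pair(SSEType.E, SSEType.E): 1.0,
    _pair(SSEType.C, SSEType.C): 1.0,
    _pair(SSEType.H, SSEType.E): 0.0,
    _pair(SSEType.H, SSEType.C): 0.0,
    _pair(SSEType.E, SSEType.C): 0.0,
}


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric element-pair weights plus a per-element gap cost.

    Weights live on unordered type pairs and must lie in [0, 1]; the
    default scheme scores identical types at weight 1 and everything
    else at 0, with gap cost 0 (skipping an element is free).  Users
    wanting partial coil credit can raise w(C,H) / w(C,E) via
    :meth:`with_overrides` or a config file.
    """

    weights: Mapping[TypePair, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    gap_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_cost < 0:
            raise ValueError(f"gap_cost must be non-negative, got {self.gap_cost}")
        merged = dict(_DEFAULT_WEIGHTS)
        merged.update(self.weights)
        for pair, w in merged.items():
            if not 0.0 <= w <= 1.0:
                names = "/".join(sorted(t.value for t in pair))
                raise ValueError(f"weight for pair {names} must be in [0,1], got {w}")
        object.__setattr__(self, "weights", merged)

    def weight(self, a: SSEType, b: SSEType) -> float:
        return self.weights[_pair(a, b)]

    def with_overrides(
        self, overrides: Mapping[str, float], gap_cost: float | None = None
    ) -> "ScoringScheme":
        """Return a new scheme with string-keyed overrides like ``"HE": 0.2``."""
        weights = dict(self.weights)
        for key, w in overrides.items():
            letters = [c for c in key.upper() if c in "HEC"]
            if len(letters) != 2:
                raise ValueError(
                    f"scheme key {key!r} must name two states from H/E/C"
                )
            weights[_pair(SSEType(letters[0]), SSEType(letters[1]))] = float(w)
        return ScoringScheme(
            weights, self.gap_cost if gap_cost is None else gap_cost
        )

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "ScoringScheme":
        """Load overrides from a flat ``key = value`` config file.

        Keys are unordered type pairs (``HH``, ``HE``, ``CE`` ... any
        separator) or ``gap_cost``; lines starting with ``#`` are
        comments.
        """
        overrides: Dict[str, float] = {}
        gap_cost: float | None = None
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed scheme config line {lineno}: {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            try:
                val = float(value)
            except ValueError:
                raise ValueError(
                    f"non-numeric value on scheme config line {lineno}: {value!r}"
                ) from None
            if key.lower() in ("gap", "gap_cost", "gapcost"):
                gap_cost = val
            else:
                overrides[key] = val
        return cls().with_overrides(overrides, gap_cost=gap_cost)


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning two element sequences.

    ``total_score`` is in residue units and bounded by the smaller
    residue length; ``ssea_score`` is the normalized similarity in
    [0, 1]; ``pairs`` lists matched element index pairs (strictly
    increasing in both coordinates).
    """

    id_a: str
    id_b: str
    total_score: float
    ssea_score: float
    pairs: Tuple[Tuple[int, int], ...]


def element_score(a: Element, b: Element, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Alignment score between two elements: w(type_a, type_b) * min(L_a, L_b)."""
    return scheme.weight(a.sse_type, b.sse_type) * min(a.length, b.length)


def _score_matrix(
    a: ElementSequence, b: ElementSequence, scheme: ScoringScheme
) -> np.ndarray:
    ta = np.array([e.sse_type.value for e in a])
    tb = np.array([e.sse_type.value for e in b])
    la = np.array([e.length for e in a], dtype=float)
    lb = np.array([e.length for e in b], dtype=float)
    w = np.empty((len(a), len(b)))
    for i, sa in enumerate(SSEType):
        for sb in SSEType:
            w[np.ix_(ta == sa.value, tb == sb.value)] = scheme.weight(sa, sb)
    return w * np.minimum.outer(la, lb)


def _fill_dp(S: np.ndarray, gap: float) -> np.ndarray:
    m, n = S.shape
    F = np.zeros((m + 1, n + 1))
    if gap == 0.0:
        # F(i,j) = max(F(i-1,j), F(i,j-1), F(i-1,j-1)+S) reduces to a
        # running maximum along each row, so rows vectorize.
        for i in range(1, m + 1):
            F[i] = np.maximum.accumulate(
                np.concatenate(([0.0], np.maximum(F[i - 1, 1:], F[i - 1, :-1] + S[i - 1])))
            )
    else:
        F[0] = -gap * np.arange(n + 1)
        for i in range(1, m + 1):
            prev, cur = F[i - 1], F[i]
            cur[0] = prev[0] - gap
            row = S[i - 1]
            for j in range(1, n + 1):
                cur[j] = max(
                    prev[j - 1] + row[j - 1], prev[j] - gap, cur[j - 1] - gap
                )
        # global-with-free-end-gaps is not intended here; nonzero gap cost
        # charges every skipped element, including terminal ones.
    return F


def align(
    a: ElementSequence,
    b: ElementSequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentResult:
    """Align two element sequences and return the normalized similarity.

    Elements are never split.  Traceback tie-breaking prefers the
    diagonal move, then skipping in ``a``, then skipping in ``b``, so
    the reported pairs are deterministic; the total score does not
    depend on the tie-break.
    """
    S = _score_matrix(a, b, scheme)
    F = _fill_dp(S, scheme.gap_cost)
    total = float(F[-1, -1])

    pairs: List[Tuple[int, int]] = []
    i, j = len(a), len(b)
    gap = scheme.gap_cost
    while i > 0 and j > 0:
        here = F[i, j]
        if np.isclose(here, F[i - 1, j - 1] + S[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif np.isclose(here, F[i - 1, j] - gap):
            i -= 1
        else:
            j -= 1
    pairs.reverse()

    denom = (a.residue_length + b.residue_length) / 2.0
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        total_score=total,
        ssea_score=total / denom,
        pairs=tuple(pairs),
    )


def ssea_score(
    a: ElementSequence, b: ElementSequence, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Normalized SSEA similarity in [0, 1] (convenience wrapper)."""
    return align(a, b, scheme).ssea_score


def render_alignment(a: ElementSequence, b: ElementSequence, result: AlignmentResult) -> str:
    """Human-readable rendering of the matched element pairs."""
    lines = [
        f"# {result.id_a} vs {result.id_b}: total={result.total_score:g} "
        f"ssea_score={result.ssea_score:.3f}"
    ]
    matched_a = {i for i, _ in result.pairs}
    matched_b = {j for _, j in result.pairs}
    for i, j in result.pairs:
        ea, eb = a.elements[i], b.elements[j]
        lines.append(
            f"  {ea.sse_type.value}{ea.length:<4d} <-> {eb.sse_type.value}{eb.length:<4d}"
        )
    for i, e in enumerate(a.elements):
        if i not in matched_a:
            lines.append(f"  {e.sse_type.value}{e.length:<4d} <-> -")
    for j, e in enumerate(b.elements):
        if j not in matched_b:
            lines.append(f"  -     <-> {e.sse_type.value}{e.length:<4d}")
    return "\n".join(lines)
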