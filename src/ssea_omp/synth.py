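"""Seeded generators of synthetic secondary-structure fixtures.

The classifier exploits a topological contrast: a beta-barrel outer
membrane protein compresses to a long alternation of 8-24 strand
elements with short coil linkers, whereas globular and helical-membrane
proteins compress to few strands, helix-dominated strings, or short
scattered strands with long coils.  The generators here emulate exactly
that contrast — alternating core elements and coil linkers with lengths
drawn uniformly from per-class ranges, optional per-residue state-flip
noise — so every pipeline stage is testable without any external
dataset.  Element lengths are uniform rather than empirical: the
simplest distribution that preserves the topology contrast.

Synthetic amino-acid sequences (random 20-letter strings, plus seeded
mutational copies at controlled identity) are attached so the
identity-based homology filter can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .classifier import LABEL_NON_OMP, LABEL_OMP, LibraryEntry, ReferenceLibrary
from .sse_model import SSEString, SSEType, compress

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

OMP_BARREL = "omp_barrel"
ALL_ALPHA = "all_alpha"
ALL_BETA_GLOBULAR = "all_beta_globular"
ALPHA_BETA = "alpha_beta"
HELICAL_MEMBRANE = "helical_membrane"


@dataclass(frozen=True)
class TopologyProfile:
    """Per-class recipe for a synthetic secondary-structure string.

    A string is built as: terminal coil, then ``n_core_elements`` core
    elements separated by coil linkers, then a terminal coil.  All
    lengths (residues) are drawn uniformly from the inclusive ranges.
    ``core_alternate_type`` lets mixed alpha/beta folds alternate two
    core element types.
    """

    class_label: str
    n_core_elements: Tuple[int, int]
    core_type: SSEType
    core_length_range: Tuple[int, int]
    linker_length_range: Tuple[int, int]
    terminal_coil_range: Tuple[int, int]
    core_alternate_type: Optional[SSEType] = None

    def __post_init__(self) -> None:
        for name in ("n_core_elements", "core_length_range",
                     "linker_length_range", "terminal_coil_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has min > max: ({lo}, {hi})")
            if lo < 1:
                raise ValueError(f"{name} must start at >= 1: ({lo}, {hi})")


# Default class recipes.  The barrel range 8-24 reflects the strand count
# of real beta-barrels; membrane-spanning strands are drawn longer (6-14)
# than globular-beta strands (3-8, with longer coils), and helical classes
# carry long helices so the cross-class element alignment stays weak.
DEFAULT_PROFILES: Dict[str, TopologyProfile] = {
    OMP_BARREL: TopologyProfile(
        class_label=OMP_BARREL,
        n_core_elements=(8, 24),
        core_type=SSEType.E,
        core_length_range=(6, 14),
        linker_length_range=(2, 6),
        terminal_coil_range=(2, 10),
    ),
    ALL_ALPHA: TopologyProfile(
        class_label=ALL_ALPHA,
        n_core_elements=(4, 10),
        core_type=SSEType.H,
        core_length_range=(10, 25),
        linker_length_range=(3, 8),
        terminal_coil_range=(2, 10),
    ),
    ALL_BETA_GLOBULAR: TopologyProfile(
        class_label=ALL_BETA_GLOBULAR,
        n_core_elements=(4, 10),
        core_type=SSEType.E,
        core_length_range=(3, 8),
        linker_length_range=(5, 14),
        terminal_coil_range=(2, 12),
    ),
    ALPHA_BETA: TopologyProfile(
        class_label=ALPHA_BETA,
        n_core_elements=(6, 12),
        core_type=SSEType.E,
        core_length_range=(4, 12),
        linker_length_range=(3, 8),
        terminal_coil_range=(2, 10),
        core_alternate_type=SSEType.H,
    ),
    HELICAL_MEMBRANE: TopologyProfile(
        class_label=HELICAL_MEMBRANE,
        n_core_elements=(6, 12),
        core_type=SSEType.H,
        core_length_range=(15, 25),
        linker_length_range=(2, 8),
        terminal_coil_range=(2, 10),
    ),
}

DEFAULT_COUNTS: Dict[str, int] = {
    OMP_BARREL: 40,
    ALL_ALPHA: 20,
    ALL_BETA_GLOBULAR: 20,
    ALPHA_BETA: 10,
    HELICAL_MEMBRANE: 10,
}


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Full recipe for a labeled synthetic library plus held-out queries.

    ``seed`` fully determines the output; ``noise`` is the independent
    per-residue probability of flipping a state to a uniformly random
    *other* state (default 0.02, a mild imperfect-prediction stand-in).
    """

    n_per_class: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    queries_per_class: Mapping[str, int] = field(
        default_factory=lambda: {k: 2 for k in DEFAULT_COUNTS}
    )
    seed: int = 0
    noise: float = 0.02
    profiles: Mapping[str, TopologyProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise < 1.0:
            raise ValueError(f"noise must be in [0,1), got {self.noise}")
        for label, n in self.n_per_class.items():
            if n < 0:
                raise ValueError(f"negative count for class {label!r}")
            if label not in self.profiles:
                raise ValueError(f"no profile for class {label!r}")


def generate_sse(
    profile: TopologyProfile,
    rng: np.random.Generator,
    id: str = "synthetic",
    noise: float = 0.0,
) -> SSEString:
    """Draw one synthetic secondary-structure string from a profile."""

    def draw(rng_range: Tuple[int, int]) -> int:
        return int(rng.integers(rng_range[0], rng_range[1] + 1))

    n_core = draw(profile.n_core_elements)
    parts: List[str] = ["C" * draw(profile.terminal_coil_range)]
    for k in range(n_core):
        if k > 0:
            parts.append("C" * draw(profile.linker_length_range))
        core = profile.core_type
        if profile.core_alternate_type is not None and k % 2 == 1:
            core = profile.core_alternate_type
        parts.append(core.value * draw(profile.core_length_range))
    parts.append("C" * draw(profile.terminal_coil_range))
    states = "".join(parts)

    if noise > 0.0:
        chars = np.frombuffer(states.encode(), dtype="S1").astype("U1")
        flip = rng.random(len(chars)) < noise
        alternatives = {"H": "EC", "E": "HC", "C": "HE"}
        for idx in np.flatnonzero(flip):
            chars[idx] = alternatives[str(chars[idx])][int(rng.integers(2))]
        states = "".join(chars)
    return SSEString(id, states)


def random_aa_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random 20-letter amino-acid string."""
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def mutate_sequence(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Seeded point-mutated copy with approximately the given identity.

    Exactly ``round((1-identity)*len)`` positions are substituted with a
    random different residue, giving a controlled global identity for
    equal-length pairs (no indels).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0,1], got {identity}")
    n_mut = round((1.0 - identity) * len(seq))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        others = AMINO_ACIDS.replace(current, "")
        chars[pos] = others[int(rng.integers(len(others)))]
    return "".join(chars)


def generate_library(
    spec: SyntheticLibrarySpec = SyntheticLibrarySpec(),
) -> Tuple[ReferenceLibrary, List[Tuple[SSEString, str]]]:
    """Build the labeled reference library and a disjoint held-out query set.

    Barrel instances are labeled OMP, every other class non-OMP.  Each
    entry carries a random amino-acid sequence of matching length so the
    identity filter can run.  Identical seeds give identical output.
    """
    n_omp = sum(n for lbl, n in spec.n_per_class.items() if lbl == OMP_BARREL)
    n_non = sum(n for lbl, n in spec.n_per_class.items() if lbl != OMP_BARREL)
    if n_omp == 0 or n_non == 0:
        raise ValueError(
            "library spec must request at least one OMP (omp_barrel) and one "
            "non-OMP class instance"
        )
    rng = np.random.default_rng(spec.seed)
    entries: List[LibraryEntry] = []
    for class_label in sorted(spec.n_per_class):
        profile = spec.profiles[class_label]
        label = LABEL_OMP if class_label == OMP_BARREL else LABEL_NON_OMP
        for k in range(spec.n_per_class[class_label]):
            entry_id = f"{class_label}_{k:03d}"
            sse = generate_sse(profile, rng, id=entry_id, noise=spec.noise)
            aa = random_aa_sequence(len(sse), rng)
            entries.append(LibraryEntry(entry_id, label, compress(sse), aa))

    queries: List[Tuple[SSEString, str]] = []
    for class_label in sorted(spec.queries_per_class):
        profile = spec.profiles[class_label]
        label = LABEL_OMP if class_label == OMP_BARREL else LABEL_NON_OMP
        for k in range(spec.queries_per_class.get(class_label, 0)):
            query_id = f"query_{class_label}_{k:03d}"
            queries.append(
                (generate_sse(profile, rng, id=query_id, noise=spec.noise), label)
            )
    return ReferenceLibrary(entries), queries


def write_fixture_dir(
    spec: SyntheticLibrarySpec, out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Materialise a fixture as files: SSE FASTA, manifest TSV, truth TSV."""
    from .sse_model import write_sse_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib, queries = generate_library(spec)

    manifest = out / "library.tsv"
    lib.to_manifest(manifest)
    sse_fasta = out / "library_sse.fasta"
    write_sse_fasta((e.elements.expand() for e in lib), sse_fasta)
    queries_fasta = out / "queries_sse.fasta"
    write_sse_fasta((q for q, _ in queries), queries_fasta)
    truth = out / "query_labels.tsv"
    with open(truth, "w") as fh:
        fh.write("id\tlabel\n")
        for q, label in queries:
            fh.write(f"{q.id}\t{label}\n")
    return {
        "manifest": manifest,
        "library_sse": sse_fasta,
        "queries_sse": queries_fasta,
        "query_labels": truth,
    }
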