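"""Domain types for 3-state secondary structure and its element encoding.

A protein's secondary structure is represented per residue over the
three-letter alphabet H (helix), E (strand), C (coil).  For element
alignment the per-residue string is run-length encoded into *elements*:
maximal runs of one state, each carrying its residue length L.  A
beta-barrel outer membrane protein compresses to a long alternation of
E elements and short coils; that topological signature is what the
alignment downstream exploits.

Readers are provided for plain FASTA-like SSE files, PSIPRED output
(``.ss2`` vertical and ``.horiz`` dialects) and DSSP-style 8-state
strings (reduced to 3 states).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union


class SSEFormatError(ValueError):
    """Raised when a secondary-structure input is malformed."""


class SSEType(str, enum.Enum):
    """One of the three admissible secondary-structure states."""

    H = "H"  # helix
    E = "E"  # strand
    C = "C"  # coil

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value

    @classmethod
    def from_char(cls, ch: str, position: int | None = None) -> "SSEType":
        """Parse a single state character (case-insensitive, no coercion)."""
        try:
            return cls(ch.upper())
        except ValueError:
            where = "" if position is None else f" at position {position}"
            raise SSEFormatError(
                f"invalid secondary-structure character {ch!r}{where}; "
                "expected one of H, E, C"
            ) from None


# 8-state DSSP codes -> 3 states, PSIPRED-style convention (B -> E).
_DSSP_REDUCTION = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", " ": "C", "-": "C", "C": "C",
}


@dataclass(frozen=True)
class SSEString:
    """A protein's per-residue 3-state secondary structure.

    Parameters
    ----------
    id : str
        Text identifier of the protein.
    states : str
        One character per residue, each in {H, E, C}.  Lower case is
        accepted and upper-cased; anything else raises
        :class:`SSEFormatError` naming the offending position.
    """

    id: str
    states: str

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise SSEFormatError(f"empty secondary-structure string for {self.id!r}")
        upper = self.states.upper()
        for i, ch in enumerate(upper):
            if ch not in ("H", "E", "C"):
                raise SSEFormatError(
                    f"invalid secondary-structure character {ch!r} at position {i} "
                    f"in {self.id!r}; expected one of H, E, C"
                )
        object.__setattr__(self, "states", upper)

    def __len__(self) -> int:
        return len(self.states)

    def compress(self) -> "ElementSequence":
        return compress(self)


@dataclass(frozen=True)
class Element:
    """A maximal run of one secondary-structure state.

    ``length`` is the run length in residues (the L_i entering the
    element alignment score).
    """

    sse_type: SSEType
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"element length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class ElementSequence:
    """Run-length encoded secondary structure: ordered (type, length) elements.

    Invariants: adjacent elements differ in type (runs are maximal) and
    the element lengths sum to the residue length of the originating
    string.
    """

    id: str
    elements: Tuple[Element, ...]

    def __post_init__(self) -> None:
        elements = tuple(self.elements)
        if not elements:
            raise ValueError(f"element sequence {self.id!r} is empty")
        for prev, cur in zip(elements, elements[1:]):
            if prev.sse_type == cur.sse_type:
                raise ValueError(
                    f"adjacent elements of equal type {prev.sse_type} in {self.id!r}; "
                    "runs must be maximal"
                )
        object.__setattr__(self, "elements", elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[Element]:
        return iter(self.elements)

    @property
    def residue_length(self) -> int:
        """Total number of residues (sum of element lengths)."""
        return sum(e.length for e in self.elements)

    def expand(self) -> SSEString:
        """Inverse of :func:`compress`: reconstruct the per-residue string."""
        return SSEString(
            self.id, "".join(e.sse_type.value * e.length for e in self.elements)
        )

    def type_string(self) -> str:
        """The shortened string, e.g. ``"HCEH"``."""
        return "".join(e.sse_type.value for e in self.elements)

    def lengths(self) -> Tuple[int, ...]:
        return tuple(e.length for e in self.elements)


def compress(s: Union[SSEString, str], id: str = "query") -> ElementSequence:
    """Run-length encode a secondary-structure string into elements.

    ``HHHHCCCCCEEEEEHHHH`` shortens to H, C, E, H with lengths
    4, 5, 5, 4.  Expanding the result reproduces the input exactly.
    """
    if isinstance(s, str):
        s = SSEString(id, s)
    elements: List[Element] = []
    cur = s.states[0]
    run = 1
    for ch in s.states[1:]:
        if ch == cur:
            run += 1
        else:
            elements.append(Element(SSEType(cur), run))
            cur, run = ch, 1
    elements.append(Element(SSEType(cur), run))
    return ElementSequence(s.id, tuple(elements))


def reduce_dssp(dssp_states: str, id: str = "query") -> SSEString:
    """Reduce an 8-state DSSP structure string to 3 states.

    Mapping: H, G, I -> H; E, B -> E; T, S, blank, ``-`` -> C.  The
    strand-friendly ``B -> E`` convention is used (bridge residues in a
    barrel belong with the strands).  3-state input passes through
    unchanged.
    """
    out = []
    for i, ch in enumerate(dssp_states):
        try:
            out.append(_DSSP_REDUCTION[ch.upper() if ch != " " else ch])
        except KeyError:
            raise SSEFormatError(
                f"unknown DSSP state {ch!r} at position {i}"
            ) from None
    if not out:
        raise SSEFormatError(f"empty DSSP string for {id!r}")
    return SSEString(id, "".join(out))


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_psipred(path: Union[str, Path], dialect: str = "ss2") -> SSEString:
    """Read a PSIPRED output file into an :class:`SSEString`.

    Parameters
    ----------
    path : path
        PSIPRED output file.
    dialect : {"ss2", "horiz"}
        ``ss2`` is the vertical format (columns: index, residue, state,
        pC, pH, pE); the state column is taken as PSIPRED's call even
        where it disagrees with the probability argmax.  ``horiz`` is
        the human-readable format; the ``Pred:`` lines are concatenated.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "ss2":
        return _read_ss2(text, path.stem)
    if dialect == "horiz":
        return _read_horiz(text, path.stem)
    raise ValueError(f"unknown PSIPRED dialect {dialect!r}; expected 'ss2' or 'horiz'")


def _read_ss2(text: str, id: str) -> SSEString:
    states: List[str] = []
    expected_idx = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise SSEFormatError(f"malformed .ss2 line {lineno}: {line!r}")
        try:
            idx = int(fields[0])
        except ValueError:
            raise SSEFormatError(
                f"malformed .ss2 residue index on line {lineno}: {fields[0]!r}"
            ) from None
        if idx != expected_idx:
            raise SSEFormatError(
                f".ss2 residue index mismatch on line {lineno}: "
                f"expected {expected_idx}, found {idx}"
            )
        expected_idx += 1
        states.append(SSEType.from_char(fields[2], position=idx - 1).value)
    if not states:
        raise SSEFormatError(f"no residue rows found in .ss2 input {id!r}")
    return SSEString(id, "".join(states))


def _read_horiz(text: str, id: str) -> SSEString:
    chunks: List[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("Pred:"):
            chunks.append(line[len("Pred:"):].strip())
    if not chunks:
        raise SSEFormatError(f"no 'Pred:' lines found in .horiz input {id!r}")
    return SSEString(id, "".join(chunks))


def read_sse_fasta(path: Union[str, Path]) -> List[SSEString]:
    """Read a plain FASTA-like SSE file: ``>id`` headers then H/E/C lines."""
    path = Path(path)
    records: List[SSEString] = []
    cur_id: str | None = None
    cur_lines: List[str] = []

    def flush() -> None:
        if cur_id is not None:
            if not cur_lines:
                raise SSEFormatError(f"record {cur_id!r} has no sequence lines")
            records.append(SSEString(cur_id, "".join(cur_lines)))

    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            cur_id = line[1:].split()[0] if line[1:].strip() else ""
            if not cur_id:
                raise SSEFormatError("FASTA header with empty identifier")
            cur_lines = []
        else:
            if cur_id is None:
                raise SSEFormatError("sequence line before first '>' header")
            cur_lines.append(line)
    flush()
    if not records:
        raise SSEFormatError(f"no records found in {path}")
    return records


def write_sse_fasta(records: Iterable[SSEString], path: Union[str, Path]) -> None:
    """Write SSE strings in the plain FASTA-like format (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.states), 60):
                fh.write(rec.states[i : i + 60] + "\n")


def read_sse_auto(path: Union[str, Path]) -> List[SSEString]:
    """Read SSE input, sniffing the format from content.

    Recognises plain FASTA-like files, PSIPRED ``.ss2`` and ``.horiz``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ss2":
        return [read_psipred(path, "ss2")]
    if suffix == ".horiz":
        return [read_psipred(path, "horiz")]
    text = path.read_text()
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            return read_sse_fasta(path)
        if stripped.startswith("Pred:"):
            return [read_psipred(path, "horiz")]
        if stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) >= 3 and fields[0].isdigit():
            return [read_psipred(path, "ss2")]
        break
    raise SSEFormatError(f"could not determine SSE format of {path}")
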