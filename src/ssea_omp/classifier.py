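"""Nearest-neighbour OMP discrimination against a labeled reference library.

A query's similarity to every library entry is measured by the
normalized SSEA score; the prediction score is the difference between
its best OMP hit and its best non-OMP hit,

    Pred_Score = SSEA_Score_max,OMP - SSEA_Score_max,non-OMP,

and the query is called an OMP when Pred_Score exceeds the decision
threshold (strictly; the default threshold is 0).  Because both maxima
lie in [0, 1], Pred_Score lies in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

from .sse_model import ElementSequence, SSEFormatError, compress, read_sse_auto
from .ssea_align import DEFAULT_SCHEME, ScoringScheme, align

logger = logging.getLogger(__name__)

LABEL_OMP = "OMP"
LABEL_NON_OMP = "non-OMP"


class LibraryError(ValueError):
    """Raised for invalid reference libraries (missing class, duplicate ids)."""


@dataclass(frozen=True)
class LibraryEntry:
    id: str
    label: str  # LABEL_OMP or LABEL_NON_OMP
    elements: ElementSequence
    aa_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (LABEL_OMP, LABEL_NON_OMP):
            raise LibraryError(
                f"entry {self.id!r} has label {self.label!r}; "
                f"expected {LABEL_OMP!r} or {LABEL_NON_OMP!r}"
            )

    @property
    def is_omp(self) -> bool:
        return self.label == LABEL_OMP


class ReferenceLibrary:
    """Labeled collection of element sequences (the classifier's library).

    Must contain at least one OMP and one non-OMP entry (both maxima in
    the prediction score need a candidate); ids must be unique.
    Amino-acid sequences are optional and only needed by the
    identity-based homology filter.
    """

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries: Tuple[LibraryEntry, ...] = tuple(entries)
        seen = set()
        for e in self.entries:
            if e.id in seen:
                raise LibraryError(f"duplicate library id {e.id!r}")
            seen.add(e.id)
        if not any(e.is_omp for e in self.entries):
            raise LibraryError("library contains no OMP entries")
        if not any(not e.is_omp for e in self.entries):
            raise LibraryError("library contains no non-OMP entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def omps(self) -> List[LibraryEntry]:
        return [e for e in self.entries if e.is_omp]

    def non_omps(self) -> List[LibraryEntry]:
        return [e for e in self.entries if not e.is_omp]

    def without(self, entry_id: str) -> List[LibraryEntry]:
        """Entries minus the named one (leave-one-out helper); plain list
        because the remainder may transiently lack a class."""
        return [e for e in self.entries if e.id != entry_id]

    # -- manifest I/O -------------------------------------------------

    @classmethod
    def from_manifest(cls, path: Union[str, Path]) -> "ReferenceLibrary":
        """Load a library from a TSV manifest.

        Columns (header required): ``id``, ``label`` (exactly ``OMP`` /
        ``non-OMP``), ``sse`` (path to an SSE file, relative to the
        manifest, or an inline H/E/C string), optional ``fasta``
        (path to the amino-acid FASTA) or ``aa_sequence`` (inline).
        """
        path = Path(path)
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        if not lines:
            raise LibraryError(f"empty manifest {path}")
        header = lines[0].rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for required in ("id", "label", "sse"):
            if required not in cols:
                raise LibraryError(
                    f"manifest {path} lacks required column {required!r}"
                )
        entries: List[LibraryEntry] = []
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(cols):
                fields += [""] * (len(cols) - len(fields))
            entry_id = fields[cols["id"]].strip()
            label = fields[cols["label"]].strip()
            sse_field = fields[cols["sse"]].strip()
            if not entry_id or not sse_field:
                raise LibraryError(f"manifest {path} line {lineno}: missing id or sse")
            if set(sse_field.upper()) <= set("HEC"):
                elements = compress(sse_field, id=entry_id)
            else:
                sse_path = path.parent / sse_field
                records = read_sse_auto(sse_path)
                match = [r for r in records if r.id == entry_id] or records[:1]
                elements = compress(match[0].states, id=entry_id)
            aa: Optional[str] = None
            if "aa_sequence" in cols and fields[cols["aa_sequence"]].strip():
                aa = fields[cols["aa_sequence"]].strip().upper()
            elif "fasta" in cols and fields[cols["fasta"]].strip():
                aa = _read_single_fasta(path.parent / fields[cols["fasta"]].strip(), entry_id)
            entries.append(LibraryEntry(entry_id, label, elements, aa))
        return cls(entries)

    def to_manifest(self, path: Union[str, Path]) -> None:
        """Write the library as a TSV manifest with inline SSE strings."""
        with open(path, "w") as fh:
            fh.write("id\tlabel\tsse\taa_sequence\n")
            for e in self.entries:
                fh.write(
                    f"{e.id}\t{e.label}\t{e.elements.expand().states}\t"
                    f"{e.aa_sequence or ''}\n"
                )


def _read_single_fasta(path: Path, entry_id: str) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise LibraryError(f"no FASTA records in {path}")
    for rec in records:
        if rec.id == entry_id:
            return str(rec.seq).upper()
    return str(records[0].seq).upper()


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of classifying one query against the library."""

    query_id: str
    score_max_omp: float
    score_max_nonomp: float
    pred_score: float
    call: str
    top_omp_hit: str

    @property
    def is_omp_call(self) -> bool:
        return self.call == LABEL_OMP


def predict(
    query: ElementSequence,
    lib: Union[ReferenceLibrary, Sequence[LibraryEntry]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = 0.0,
) -> PredictionResult:
    """Classify a query by its best OMP and best non-OMP library similarity.

    Arg-max ties are broken by library order (first maximal entry).  A
    library lacking either class is a configuration error.
    """
    entries = list(lib)
    omps = [e for e in entries if e.is_omp]
    nonomps = [e for e in entries if not e.is_omp]
    if not omps or not nonomps:
        raise LibraryError(
            "prediction requires at least one OMP and one non-OMP library entry"
        )

    best_omp, best_omp_hit = -1.0, omps[0].id
    for e in omps:
        s = align(query, e.elements, scheme).ssea_score
        if s > best_omp:
            best_omp, best_omp_hit = s, e.id
    best_non = -1.0
    for e in nonomps:
        s = align(query, e.elements, scheme).ssea_score
        if s > best_non:
            best_non = s

    pred = best_omp - best_non
    call = LABEL_OMP if pred > threshold else LABEL_NON_OMP
    return PredictionResult(
        query_id=query.id,
        score_max_omp=best_omp,
        score_max_nonomp=best_non,
        pred_score=pred,
        call=call,
        top_omp_hit=best_omp_hit,
    )


def predict_batch(
    queries: Iterable[ElementSequence],
    lib: Union[ReferenceLibrary, Sequence[LibraryEntry]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = 0.0,
) -> List[PredictionResult]:
    """Classify many queries; a malformed query is logged and skipped."""
    results: List[PredictionResult] = []
    for q in queries:
        try:
            results.append(predict(q, lib, scheme, threshold))
        except (SSEFormatError, ValueError) as exc:
            if isinstance(exc, LibraryError):
                raise
            qid = getattr(q, "id", "<unknown>")
            logger.warning("skipping malformed query %r: %s", qid, exc)
    return results


def calibrate_threshold(
    lib: ReferenceLibrary,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    target_fpr: float = 0.01,
) -> float:
    """Choose the decision threshold hitting a target false-positive rate.

    Runs leave-one-out predictions over the library and returns the
    smallest threshold alpha (among the observed non-OMP prediction
    scores) such that the fraction of non-OMP entries with
    ``pred_score > alpha`` is at most ``target_fpr``.
    """
    if not 0.0 < target_fpr < 1.0:
        raise ValueError(f"target_fpr must be in (0,1), got {target_fpr}")
    non_scores: List[float] = []
    for entry in lib:
        remainder = lib.without(entry.id)
        try:
            res = predict(entry.elements, remainder, scheme)
        except LibraryError:
            continue  # remainder lost a class; entry cannot be scored
        if not entry.is_omp:
            non_scores.append(res.pred_score)
    if not non_scores:
        raise LibraryError("no non-OMP entry could be scored during calibration")
    candidates = sorted(set(non_scores))
    n = len(non_scores)
    for alpha in candidates:
        fpr = sum(1 for s in non_scores if s > alpha) / n
        if fpr <= target_fpr:
            return alpha
    logger.warning("degenerate calibration: all non-OMP scores tied; returning max")
    return candidates[-1]
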