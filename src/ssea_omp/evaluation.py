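"""Performance assessment: confusion metrics, ROC/AUC, homology-filtered LOO.

The classifier is benchmarked by leave-one-out (LOO) over a labeled
library: each entry in turn is held out, the remainder — after stringent
homology filtering against the held-out protein — serves as the library,
and the held-out protein is classified.  Aggregated calls give the
confusion counts and the four standard two-class measures

    Ac  = (tp + tn) / (tp + fp + fn + tn)
    Sn  = tp / (tp + fn)
    Sp  = tn / (tn + fp)
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

and sweeping the decision threshold alpha over all observed prediction
scores yields the ROC curve and its AUC.

Homology filtering retains only library entries that share, with the
test protein, a global (Needleman-Wunsch) sequence identity strictly
below 25% and — when the corresponding search hooks are supplied — a
BLAST e-value strictly above 0.01 and a PSI-BLAST e-value strictly
above 0.01.  The e-value stages are pluggable callables because the
search tools themselves are external; absent hooks skip those stages
with a prominent log line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .classifier import (
    LABEL_NON_OMP,
    LABEL_OMP,
    LibraryEntry,
    LibraryError,
    ReferenceLibrary,
    predict,
)
from .ssea_align import DEFAULT_SCHEME, ScoringScheme

logger = logging.getLogger(__name__)

# hook signature: (test_aa_sequence, library_entry) -> e-value, or None for "no hit"
EvalueHook = Callable[[str, LibraryEntry], Optional[float]]


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    """Ac, Sn, Sp as fractions in [0, 1]; MCC in [-1, 1]."""

    ac: float
    sn: float
    sp: float
    mcc: float


def metrics(c: ConfusionCounts) -> EvalMetrics:
    """Accuracy, sensitivity, specificity and Matthews correlation.

    Sn requires at least one positive and Sp at least one negative; a
    zero MCC denominator (a degenerate row or column) yields MCC = 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero confusion counts")
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("metrics require at least one positive and one negative")
    ac = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0.0 else (c.tp * c.tn - c.fp * c.fn) / denom
    return EvalMetrics(ac=ac, sn=sn, sp=sp, mcc=mcc)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """ROC points swept over the decision threshold alpha.

    ``points`` are (fp, tp) instance counts in order of decreasing
    threshold (monotone non-decreasing in both coordinates); ``auc`` is
    the trapezoidal area under the rate-scaled curve.
    """

    points: Tuple[Tuple[int, int], ...]
    auc: float
    n_pos: int
    n_neg: int

    def rates(self) -> Tuple[Tuple[float, float], ...]:
        return tuple((fp / self.n_neg, tp / self.n_pos) for fp, tp in self.points)


def roc(scored: Sequence[Tuple[float, bool]]) -> RocCurve:
    """ROC curve for (pred_score, is_positive) pairs.

    An item is predicted positive when its score is strictly greater
    than the threshold, matching the classifier's decision rule; all
    items tied at a threshold therefore change prediction together.
    """
    if not scored:
        raise ValueError("empty input to roc")
    n_pos = sum(1 for _, y in scored if y)
    n_neg = len(scored) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc requires at least one positive and one negative")

    order = sorted(scored, key=lambda t: -t[0])
    points: List[Tuple[int, int]] = [(0, 0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j][0] == order[i][0]:
            if order[j][1]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp, tp))
        i = j

    xs = np.array([p[0] / n_neg for p in points])
    ys = np.array([p[1] / n_pos for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=tuple(points), auc=auc, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# global identity (Needleman-Wunsch)
# ---------------------------------------------------------------------------

_aligner = None


def _get_aligner(gap_open: float, gap_extend: float, matrix: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # biopython convention: open_gap_score applies to the first gapped
    # position, extend to the rest; BLAST's -11/-1 means first position
    # costs 11+1.
    aligner.open_gap_score = -(abs(gap_open) + abs(gap_extend))
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_identity(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> float:
    """Global pairwise identity between two amino-acid sequences.

    Needleman-Wunsch with BLOSUM62 and affine gaps (open 11 / extend 1,
    BLAST-like); identity is the number of identical aligned positions
    divided by the alignment length including gap columns.  The 25%
    cutoff downstream is sensitive to these parameters, so they are
    exposed.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_identity requires non-empty sequences")
    aligner = _get_aligner(gap_open, gap_extend, matrix)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


# ---------------------------------------------------------------------------
# homology filtering
# ---------------------------------------------------------------------------

STAGE_IDENTITY = "identity"
STAGE_SEARCH = "search_evalue"
STAGE_PROFILE = "profile_evalue"
ALL_STAGES = frozenset({STAGE_IDENTITY, STAGE_SEARCH, STAGE_PROFILE})


@dataclass(frozen=True)
class FilterPolicy:
    """Which homology-filter stages run and with what cutoffs.

    An entry survives only if it passes *every* enabled stage: global
    identity strictly below ``identity_max`` (default 0.25), search
    e-value strictly above ``evalue_min`` (default 0.01), profile-search
    e-value strictly above ``evalue_min``.
    """

    identity_max: float = 0.25
    evalue_min: float = 0.01
    stages: frozenset = frozenset({STAGE_IDENTITY})

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_max <= 1.0:
            raise ValueError(f"identity_max must be in (0,1], got {self.identity_max}")
        if self.evalue_min <= 0:
            raise ValueError(f"evalue_min must be > 0, got {self.evalue_min}")
        stages = frozenset(self.stages)
        unknown = stages - ALL_STAGES
        if unknown:
            raise ValueError(f"unknown filter stages: {sorted(unknown)}")
        object.__setattr__(self, "stages", stages)


def filter_library(
    test_entry: LibraryEntry,
    lib: Union[ReferenceLibrary, Sequence[LibraryEntry]],
    policy: FilterPolicy,
    search_hook: Optional[EvalueHook] = None,
    profile_hook: Optional[EvalueHook] = None,
) -> List[LibraryEntry]:
    """Entries of ``lib`` not detectably homologous to the test protein.

    The e-value hooks receive ``(test_aa_sequence, entry)`` and return
    an e-value, or None for "no hit" (which passes).  A hook failure
    retains the entry with a logged warning (fail-open), so a broken
    search never silently shrinks the library.
    """
    entries = list(lib)
    if not policy.stages:
        return entries

    if STAGE_IDENTITY in policy.stages and test_entry.aa_sequence is None:
        raise LibraryError(
            f"identity filtering requested but test entry {test_entry.id!r} "
            "has no amino-acid sequence"
        )
    hooks: List[Tuple[str, Optional[EvalueHook]]] = [
        (STAGE_SEARCH, search_hook),
        (STAGE_PROFILE, profile_hook),
    ]
    for stage, hook in hooks:
        if stage in policy.stages and hook is None:
            logger.warning(
                "filter stage %s requested but no hook supplied; stage SKIPPED "
                "(first-procedure-only behaviour)", stage,
            )

    kept: List[LibraryEntry] = []
    for entry in entries:
        if STAGE_IDENTITY in policy.stages:
            if entry.aa_sequence is None:
                raise LibraryError(
                    f"identity filtering requires amino-acid sequences; "
                    f"entry {entry.id!r} has none"
                )
            if global_identity(test_entry.aa_sequence, entry.aa_sequence) >= policy.identity_max:
                continue
        rejected = False
        for stage, hook in hooks:
            if stage not in policy.stages or hook is None:
                continue
            try:
                evalue = hook(test_entry.aa_sequence or "", entry)
            except Exception as exc:  # fail-open, flagged
                logger.warning(
                    "%s hook failed for entry %r (%s); entry retained",
                    stage, entry.id, exc,
                )
                continue
            if evalue is not None and evalue <= policy.evalue_min:
                rejected = True
                break
        if not rejected:
            kept.append(entry)
    return kept


def evalue_hook_from_tsv(path: Union[str, Path]) -> EvalueHook:
    """Adapt a tabular homology-search output file into an e-value hook.

    Reads BLAST outfmt-6-style TSV (query id, subject id, ..., e-value
    in column 11, or a 3-column query/subject/e-value layout) and
    returns the recorded e-value for (test id, entry id) pairs; pairs
    absent from the file count as "no hit".  The test protein is
    identified by matching the entry ids in the file, so hooks built
    this way key on ids rather than raw sequences.
    """
    table: Dict[Tuple[str, str], float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 12:
            q, s, e = fields[0], fields[1], float(fields[10])
        elif len(fields) >= 3:
            q, s, e = fields[0], fields[1], float(fields[2])
        else:
            raise ValueError(f"unrecognised search-output line: {line!r}")
        key = (q, s)
        table[key] = min(e, table.get(key, math.inf))

    # The hook contract passes the raw test sequence, not its id, so the
    # adapter keys on the library entry id across every query row and takes
    # the most significant (smallest) recorded e-value.
    def hook_by_entry(test_seq: str, entry: LibraryEntry) -> Optional[float]:
        best: Optional[float] = None
        for (q, s), e in table.items():
            if entry.id in (q, s):
                best = e if best is None else min(best, e)
        return best

    return hook_by_entry


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------

#: pred_score assigned to LOO cases whose filtered library lost a whole
#: class; the floor of the score range, so the case is a negative call at
#: any sensible threshold.
UNPREDICTABLE_SCORE = -1.0


@dataclass(frozen=True)
class LooRecord:
    """Per-protein row of the LOO report."""

    id: str
    label: str
    pred_score: float
    call: str
    top_omp_hit: str
    n_library: int
    unpredictable: bool = False
    note: str = ""


@dataclass(frozen=True)
class LooResult:
    counts: ConfusionCounts
    metrics: EvalMetrics
    roc: RocCurve
    records: Tuple[LooRecord, ...]


def loo_evaluate(
    lib: ReferenceLibrary,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    policy: FilterPolicy = FilterPolicy(stages=frozenset()),
    threshold: float = 0.0,
    search_hook: Optional[EvalueHook] = None,
    profile_hook: Optional[EvalueHook] = None,
) -> LooResult:
    """Leave-one-out benchmark of the classifier over a labeled library.

    Each entry is held out, the remainder is homology-filtered against
    it per ``policy``, and the held-out protein is classified against
    the filtered library.  A test protein whose filtered library lost an
    entire class is recorded as unpredictable and counted as a non-OMP
    call (conservative), flagged in the per-protein report.
    """
    records: List[LooRecord] = []
    tp = fp = fn = tn = 0
    for entry in lib:
        remainder = lib.without(entry.id)
        filtered = filter_library(entry, remainder, policy, search_hook, profile_hook)
        has_omp = any(e.is_omp for e in filtered)
        has_non = any(not e.is_omp for e in filtered)
        if not (has_omp and has_non):
            lost = [] if has_omp else [LABEL_OMP]
            if not has_non:
                lost.append(LABEL_NON_OMP)
            records.append(
                LooRecord(
                    id=entry.id,
                    label=entry.label,
                    pred_score=UNPREDICTABLE_SCORE,
                    call=LABEL_NON_OMP,
                    top_omp_hit="",
                    n_library=len(filtered),
                    unpredictable=True,
                    note=f"filtered library lost class(es): {','.join(lost)}",
                )
            )
        else:
            res = predict(entry.elements, filtered, scheme, threshold)
            records.append(
                LooRecord(
                    id=entry.id,
                    label=entry.label,
                    pred_score=res.pred_score,
                    call=res.call,
                    top_omp_hit=res.top_omp_hit,
                    n_library=len(filtered),
                )
            )
        rec = records[-1]
        if rec.label == LABEL_OMP:
            if rec.call == LABEL_OMP:
                tp += 1
            else:
                fn += 1
        else:
            if rec.call == LABEL_OMP:
                fp += 1
            else:
                tn += 1

    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    curve = roc([(r.pred_score, r.label == LABEL_OMP) for r in records])
    return LooResult(
        counts=counts,
        metrics=metrics(counts),
        roc=curve,
        records=tuple(records),
    )
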