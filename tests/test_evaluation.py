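"""Metrics, ROC/AUC, global identity, homology filtering, LOO protocol."""

import logging
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import ssea_omp.evaluation as ev
from ssea_omp import (
    ConfusionCounts,
    FilterPolicy,
    LABEL_NON_OMP,
    LABEL_OMP,
    LibraryEntry,
    LibraryError,
    ReferenceLibrary,
    compress,
    filter_library,
    global_identity,
    loo_evaluate,
    metrics,
    roc,
)


# -- confusion metrics ------------------------------------------------------

def test_perfect_and_chance_classifiers():
    perfect = metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
    assert (perfect.ac, perfect.sn, perfect.sp, perfect.mcc) == (1.0, 1.0, 1.0, 1.0)
    chance = metrics(ConfusionCounts(tp=25, fp=25, fn=25, tn=25))
    assert chance.ac == 0.5
    assert chance.mcc == 0.0


def test_benchmark_confusion_matrices():
    """The two stringency settings of the reference benchmark: 377 positives
    and 942 negatives with Sn 72.9%/Sp 98.1% give MCC 0.772 and Ac 90.9%;
    Sn 91.5% at the same Sp gives MCC 0.906 and Ac 96.2%."""
    strict = metrics(ConfusionCounts(tp=275, fn=102, fp=18, tn=924))
    assert strict.sn * 100 == pytest.approx(72.9, abs=0.05)
    assert strict.sp * 100 == pytest.approx(98.1, abs=0.05)
    assert strict.ac * 100 == pytest.approx(90.9, abs=0.05)
    assert strict.mcc == pytest.approx(0.772, abs=5e-4)

    lenient = metrics(ConfusionCounts(tp=345, fn=32, fp=18, tn=924))
    assert lenient.sn * 100 == pytest.approx(91.5, abs=0.05)
    assert lenient.ac * 100 == pytest.approx(96.2, abs=0.05)
    assert lenient.mcc == pytest.approx(0.906, abs=5e-4)


def test_accuracy_is_class_weighted_mix_of_sn_sp():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, fn, tn = (int(x) for x in rng.integers(1, 50, size=4))
        m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        n_pos, n_neg = tp + fn, fp + tn
        assert m.ac == pytest.approx(
            (n_pos * m.sn + n_neg * m.sp) / (n_pos + n_neg)
        )


def test_mcc_zero_for_proportional_confusion_rows():
    m = metrics(ConfusionCounts(tp=10, fp=20, fn=5, tn=10))  # rows proportional
    assert m.mcc == pytest.approx(0.0)
    # degenerate column: classifier never predicts positive
    m2 = metrics(ConfusionCounts(tp=0, fp=0, fn=10, tn=20))
    assert m2.mcc == 0.0


def test_metrics_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=5))  # no positives


# -- ROC / AUC --------------------------------------------------------------

def test_roc_toy_and_separable_cases():
    toy = [(0.9, True), (0.8, False), (0.7, True), (0.1, False)]
    assert roc(toy).auc == pytest.approx(0.75)
    separable = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
    assert roc(separable).auc == pytest.approx(1.0)


def test_roc_monotone_points_and_endpoints():
    rng = np.random.default_rng(1)
    scored = [(float(rng.random()), bool(rng.random() < 0.4)) for _ in range(50)]
    curve = roc(scored)
    assert curve.points[0] == (0, 0)
    assert curve.points[-1] == (curve.n_neg, curve.n_pos)
    for (f1, t1), (f2, t2) in zip(curve.points, curve.points[1:]):
        assert f2 >= f1 and t2 >= t1


def test_auc_equals_normalized_rank_sum():
    """Trapezoidal AUC equals the Mann-Whitney U statistic over n+ * n-
    (ties handled by the midpoint convention on both sides)."""
    rng = np.random.default_rng(2)
    for _ in range(40):
        n = int(rng.integers(4, 25))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or (~labels).all():
            continue
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        expected = u / (labels.sum() * (~labels).sum())
        assert roc(list(zip(scores, labels))).auc == pytest.approx(expected)


def test_roc_rejects_single_class():
    with pytest.raises(ValueError):
        roc([(0.5, True), (0.6, True)])


# -- global identity --------------------------------------------------------

def test_global_identity_examples():
    assert global_identity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0
    assert global_identity("AAAA", "TTTT") == 0.0
    assert global_identity("ACDEFG", "ACDEYG") == pytest.approx(5 / 6)


def test_global_identity_rejects_empty():
    with pytest.raises(ValueError):
        global_identity("", "ACD")


# -- homology filtering -----------------------------------------------------

def _aa_library():
    barrel = compress("C" + "EEEEEEEECC" * 10, id="x")
    helix = compress("C" + "HHHHHHHHHHCC" * 6, id="x")
    mk = lambda i, label, elems: LibraryEntry(f"e{i}", label, elems, aa_sequence="A" * 50)
    return [
        mk(0, LABEL_OMP, barrel),
        mk(1, LABEL_OMP, barrel),
        mk(2, LABEL_NON_OMP, helix),
        mk(3, LABEL_NON_OMP, helix),
    ]


def test_identity_cutoff_is_strict(monkeypatch):
    """Identities {0.10, 0.24, 0.25, 0.40} at cutoff 0.25 keep exactly the
    two entries strictly below the cutoff."""
    entries = _aa_library()
    identities = {"e0": 0.10, "e1": 0.24, "e2": 0.25, "e3": 0.40}
    # stub the pairwise identity; the entry is recognisable by sequence
    by_seq = {e.aa_sequence + e.id[-1]: identities[e.id] for e in entries}
    entries = [
        LibraryEntry(e.id, e.label, e.elements, e.aa_sequence + e.id[-1])
        for e in entries
    ]
    monkeypatch.setattr(ev, "global_identity", lambda a, b, **kw: by_seq[b])

    test_entry = LibraryEntry(
        "test", LABEL_OMP, compress("EEEECCCC", id="test"), aa_sequence="A" * 50
    )
    kept = filter_library(
        test_entry, entries, FilterPolicy(stages=frozenset({"identity"}))
    )
    assert [e.id for e in kept] == ["e0", "e1"]


def test_self_entry_removed_by_identity_filter():
    entries = _aa_library()
    test_entry = entries[0]  # identical sequence present in the library
    kept = filter_library(
        test_entry, entries, FilterPolicy(stages=frozenset({"identity"}))
    )
    assert all(e.id != test_entry.id for e in kept)
    # every entry here shares the identical poly-A sequence, so all go
    assert kept == []


def test_empty_stages_is_noop_and_filter_is_idempotent():
    entries = _aa_library()
    test_entry = entries[0]
    assert filter_library(test_entry, entries, FilterPolicy(stages=frozenset())) == entries

    rng = np.random.default_rng(4)
    from ssea_omp import random_aa_sequence

    varied = [
        LibraryEntry(e.id, e.label, e.elements, random_aa_sequence(60, rng))
        for e in entries
    ]
    probe = LibraryEntry(
        "probe", LABEL_OMP, compress("EEEE", id="probe"), random_aa_sequence(60, rng)
    )
    policy = FilterPolicy(stages=frozenset({"identity"}))
    once = filter_library(probe, varied, policy)
    twice = filter_library(probe, once, policy)
    assert [e.id for e in once] == [e.id for e in twice]


def test_evalue_cutoff_strict_no_hit_passes_and_failure_fails_open(caplog):
    entries = _aa_library()
    test_entry = LibraryEntry(
        "t", LABEL_OMP, compress("EEEE", id="t"), aa_sequence="A" * 50
    )
    evalues = {"e0": 0.01, "e1": 0.011, "e2": None}

    def hook(test_seq, entry):
        if entry.id == "e3":
            raise RuntimeError("search backend unavailable")
        return evalues[entry.id]

    policy = FilterPolicy(stages=frozenset({"search_evalue"}))
    with caplog.at_level(logging.WARNING):
        kept = filter_library(test_entry, entries, policy, search_hook=hook)
    # e0 at exactly 0.01 fails the strict "> 0.01" rule; e1 passes;
    # e2 has no hit (passes); e3's hook failed (retained, flagged)
    assert [e.id for e in kept] == ["e1", "e2", "e3"]
    assert any("hook failed" in rec.message for rec in caplog.records)


def test_identity_stage_without_sequences_is_configuration_error():
    barrel = compress("EEEECC", id="x")
    entries = [
        LibraryEntry("a", LABEL_OMP, barrel),
        LibraryEntry("b", LABEL_NON_OMP, barrel),
    ]
    probe = LibraryEntry("p", LABEL_OMP, barrel)
    with pytest.raises(LibraryError, match="amino-acid"):
        filter_library(probe, entries, FilterPolicy(stages=frozenset({"identity"})))


def test_evalue_hook_from_tsv(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "q1\te0\t95.0\t50\t2\t0\t1\t50\t1\t50\t1e-30\t180\n"  # outfmt 6
        "q1\te1\t0.5\n"  # 3-column layout
    )
    hook = ev.evalue_hook_from_tsv(path)
    entries = _aa_library()
    assert hook("SEQ", entries[0]) == pytest.approx(1e-30)
    assert hook("SEQ", entries[1]) == pytest.approx(0.5)
    assert hook("SEQ", entries[2]) is None


# -- leave-one-out ----------------------------------------------------------

def test_loo_separable_toy(toy_library):
    result = loo_evaluate(toy_library)
    assert (result.counts.tp, result.counts.tn) == (2, 2)
    assert (result.counts.fp, result.counts.fn) == (0, 0)
    assert result.metrics.mcc == 1.0
    assert result.roc.auc == 1.0
    assert len(result.records) == 4


def test_loo_all_pass_policy_equals_no_stage_policy():
    from ssea_omp import SyntheticLibrarySpec, generate_library

    spec = SyntheticLibrarySpec(
        n_per_class={"omp_barrel": 5, "all_alpha": 5},
        queries_per_class={},
        seed=9,
        noise=0.0,
    )
    lib, _ = generate_library(spec)
    no_stages = loo_evaluate(lib, policy=FilterPolicy(stages=frozenset()))
    # identity stage enabled but every pair is far below the cutoff:
    # random sequences at ~5-15% identity all pass
    all_pass = loo_evaluate(
        lib, policy=FilterPolicy(identity_max=1.0, stages=frozenset({"identity"}))
    )
    assert no_stages.counts == all_pass.counts
    assert [r.pred_score for r in no_stages.records] == [
        r.pred_score for r in all_pass.records
    ]


def test_loo_unpredictable_case_counts_as_negative_call():
    """When filtering strips the whole OMP class for an OMP test protein,
    the case is flagged and scored as a missed positive."""
    barrel = "C" + "EEEEEEEECC" * 10
    helix = "C" + "HHHHHHHHHHCC" * 6
    entries = [
        LibraryEntry("o1", LABEL_OMP, compress(barrel, id="o1"), aa_sequence="A" * 40),
        LibraryEntry("o2", LABEL_OMP, compress(barrel, id="o2"), aa_sequence="A" * 40),
        LibraryEntry("n1", LABEL_NON_OMP, compress(helix, id="n1"), aa_sequence="W" * 40),
        LibraryEntry("n2", LABEL_NON_OMP, compress(helix, id="n2"), aa_sequence="Y" * 40),
    ]
    lib = ReferenceLibrary(entries)
    result = loo_evaluate(lib, policy=FilterPolicy(stages=frozenset({"identity"})))
    omp_records = [r for r in result.records if r.label == LABEL_OMP]
    assert all(r.unpredictable for r in omp_records)
    assert all(r.call == LABEL_NON_OMP for r in omp_records)
    assert all(r.pred_score == ev.UNPREDICTABLE_SCORE for r in omp_records)
    assert result.counts.fn == 2


def test_loo_is_deterministic_run_to_run():
    from ssea_omp import SyntheticLibrarySpec, generate_library

    spec = SyntheticLibrarySpec(
        n_per_class={"omp_barrel": 6, "all_alpha": 4, "all_beta_globular": 4},
        queries_per_class={},
        seed=13,
        noise=0.02,
    )
    lib1, _ = generate_library(spec)
    lib2, _ = generate_library(spec)
    r1, r2 = loo_evaluate(lib1), loo_evaluate(lib2)
    assert r1 == r2
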