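"""Simulator construction rules, outcome classification and metrics."""

import io
import math

import numpy as np
import pytest

from seqclip.alignment import reverse_complement
from seqclip.simbench import (
    MISSED_ADAPTER,
    OutcomeCounts,
    QualityModel,
    SimConfig,
    TRIMMED_EXACT,
    TRIMMED_LESS,
    TRIMMED_MORE,
    TRIMMED_NO_ADAPTER,
    UNTOUCHED_NO_ADAPTER,
    build_truth_pair,
    classify_outcome,
    evaluate,
    evaluate_trimmed_reads,
    mutate_by_quality,
    read_truth,
    synth_base_pair,
    write_truth,
)

CFG = SimConfig(n_pairs=1)


def _pair_with_insert(target_li, seed=0):
    """Draw pairs until the sampled insert length equals target_li."""
    rng = np.random.default_rng(seed)
    for _ in range(100_000):
        r1, r2, truth = build_truth_pair(CFG, rng)
        if truth.insert_length == target_li:
            return r1, r2, truth
    raise AssertionError("insert length never sampled")


def test_synth_base_pair_shapes(rng):
    r1, r2 = synth_base_pair(CFG, rng, "x")
    assert len(r1) == len(r2) == 75
    assert set(r1.sequence) <= set("ACGT")
    assert r1.qualities.min() >= 2 and r1.qualities.max() <= 41


def test_synth_base_pair_reproducible():
    a = synth_base_pair(CFG, np.random.default_rng(5), "x")
    b = synth_base_pair(CFG, np.random.default_rng(5), "x")
    assert a == b


def test_quality_declines_toward_3prime():
    model = QualityModel()
    rng = np.random.default_rng(0)
    samples = np.array([model.sample(75, rng) for _ in range(10_000)])
    means = samples.mean(axis=0)
    assert means[:10].mean() > means[-10:].mean() + 5


def test_no_overlap_case_leaves_pair_unchanged():
    r1, r2, truth = _pair_with_insert(150)
    assert not truth.contaminated and not truth.overlapping
    rng = np.random.default_rng(truth.insert_length)
    # read 2 is unrelated to read 1: no 50-nt reverse-complement identity
    assert reverse_complement(r1.sequence[:75]) != r2.sequence


def test_overlap_case_writes_reverse_complement():
    r1, r2, truth = _pair_with_insert(100)
    assert truth.overlapping and not truth.contaminated
    # overlap = 50 nt: read 2's 3' half mirrors read 1's 3' half up to mutation
    expected = reverse_complement(r1.sequence[25:75])
    observed = r2.sequence[25:75]
    mismatches = sum(1 for a, b in zip(expected, observed) if a != b)
    assert mismatches < 10  # only quality-driven mutations differ


def test_contaminated_case_carries_adapters():
    r1, r2, truth = _pair_with_insert(40)
    assert truth.contaminated and truth.adapter_length == 35
    mm1 = sum(1 for a, b in zip(r1.sequence[40:], CFG.adapter1) if a != b)
    mm2 = sum(1 for a, b in zip(r2.sequence[40:], CFG.adapter2) if a != b)
    assert mm1 < 8 and mm2 < 8
    exp_insert = reverse_complement(r1.sequence[:40])
    mm = sum(1 for a, b in zip(exp_insert, r2.sequence[:40]) if a != b)
    assert mm < 10


def test_truth_invariants():
    rng = np.random.default_rng(3)
    for _ in range(500):
        _, _, truth = build_truth_pair(CFG, rng)
        assert truth.contaminated == (truth.adapter_length > 0)
        assert truth.adapter_length == max(0, 75 - truth.insert_length)
        assert truth.overlapping == (75 <= truth.insert_length < 150)


def test_contaminated_fraction_matches_uniform_sampling():
    rng = np.random.default_rng(11)
    n = 20_000
    contaminated = sum(
        build_truth_pair(CFG, rng)[2].contaminated for _ in range(n)
    )
    expected = n * 75 / 201
    sd = math.sqrt(n * (75 / 201) * (1 - 75 / 201))
    assert abs(contaminated - expected) < 5 * sd


def test_mutate_all_q0_substitutes_everything(rng):
    seq = "ACGT" * 25
    out = mutate_by_quality(seq, np.zeros(100, dtype=int), rng)
    assert all(a != b for a, b in zip(seq, out))


def test_mutate_rate_matches_phred(rng):
    n = 100_000
    seq = "A" * n
    out = mutate_by_quality(seq, np.full(n, 10), rng)
    subs = sum(1 for a, b in zip(seq, out) if a != b)
    sd = math.sqrt(n * 0.1 * 0.9)
    assert abs(subs - n * 0.1) < 5 * sd


def test_mutate_high_quality_nearly_never(rng):
    seq = "A" * 10_000
    out = mutate_by_quality(seq, np.full(10_000, 60), rng)
    assert sum(1 for a, b in zip(seq, out) if a != b) <= 2


@pytest.mark.parametrize(
    "removed,adapter_len,expected",
    [
        (10, 10, TRIMMED_EXACT),
        (3, 0, TRIMMED_NO_ADAPTER),
        (12, 10, TRIMMED_MORE),
        (5, 10, TRIMMED_LESS),
        (0, 10, MISSED_ADAPTER),
        (0, 0, UNTOUCHED_NO_ADAPTER),
    ],
)
def test_classify_outcome(removed, adapter_len, expected):
    from seqclip.simbench import TruthRecord

    truth = TruthRecord(
        insert_length=75 - adapter_len,
        adapter_length=adapter_len,
        overlapping=False,
        contaminated=adapter_len > 0,
    )
    assert classify_outcome(removed, truth) == expected


def test_classification_partitions(rng):
    """Every simulated outcome lands in exactly one category."""
    counts = OutcomeCounts()
    rng_local = np.random.default_rng(2)
    n = 300
    for _ in range(n):
        _, _, truth = build_truth_pair(CFG, rng_local)
        removed = int(rng_local.integers(0, 76))
        counts.add(classify_outcome(removed, truth))
    assert counts.total == n


def test_evaluate_against_direct_computation(rng):
    """evaluate() agrees with a from-scratch recomputation on random counts."""
    for _ in range(200):
        c = OutcomeCounts(*(int(x) for x in rng.integers(0, 1000, size=6)))
        m = evaluate(c)
        tp = c.trimmed_exact
        fp = c.trimmed_no_adapter + c.trimmed_more
        fn = c.trimmed_less + c.missed_adapter
        tn = c.untouched_no_adapter
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        else:
            assert m.ppv is None
        if tp + fn:
            assert m.sen == pytest.approx(tp / (tp + fn))
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom:
            assert m.mcc == pytest.approx((tp * tn - fp * fn) / math.sqrt(denom))
            assert -1.0 <= m.mcc <= 1.0
        else:
            assert m.mcc is None
        for v in (m.ppv, m.sen, m.spec):
            if v is not None:
                assert 0.0 <= v <= 1.0


def test_evaluate_degenerate_counts():
    m = evaluate(OutcomeCounts())
    assert m.ppv is m.sen is m.spec is m.mcc is None
    perfect = evaluate(OutcomeCounts(trimmed_exact=1, untouched_no_adapter=1))
    assert perfect.ppv == perfect.sen == perfect.spec == perfect.mcc == 1.0


def test_truth_file_round_trip():
    rng = np.random.default_rng(4)
    records = []
    for i in range(20):
        _, _, truth = build_truth_pair(CFG, rng)
        records.append((f"sim_{i}", 75, truth))
    buf = io.StringIO()
    write_truth(records, buf)
    buf.seek(0)
    loaded = read_truth(buf)
    assert len(loaded) == 20
    for pair_id, lr, truth in records:
        assert loaded[pair_id] == (lr, truth)


def test_evaluate_trimmed_reads_missing_read_counts_as_fully_trimmed():
    from seqclip.simbench import TruthRecord

    truth = {
        "a": (75, TruthRecord(0, 75, False, True)),  # pure adapter, discarded
        "b": (75, TruthRecord(150, 0, False, False)),
    }
    counts = evaluate_trimmed_reads({"b": 75}, truth)
    assert counts.trimmed_exact == 1
    assert counts.untouched_no_adapter == 1
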