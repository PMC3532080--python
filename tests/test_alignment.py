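"""Alignment scoring, mismatch allowances and oracle equivalence."""

import numpy as np
import pytest

from conftest import make_read, oracle_align_pair, oracle_align_se, random_seq

from seqclip.alignment import (
    AlignmentConfig,
    DEFAULT_ALIGNMENT,
    PAIRED_END,
    SINGLE_END,
    align_adapter_3prime,
    align_pair,
    inferred_insert_length,
    max_mismatches,
    reverse_complement,
    score_overlap,
)
from seqclip.trimmer import DEFAULT_ADAPTER1, DEFAULT_ADAPTER2


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", (4, 0, 0)),
        ("ACGT", "ACGA", (2, 1, 0)),
        ("ACNT", "ACGT", (3, 0, 1)),
        ("NNNN", "ACGT", (0, 0, 4)),
        ("AAAA", "TTTT", (-4, 4, 0)),
    ],
)
def test_score_overlap(a, b, expected):
    assert score_overlap(a, b) == expected


def test_score_overlap_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        score_overlap("ACG", "AC")


@pytest.mark.parametrize(
    "length,mode,expected",
    [
        (1, PAIRED_END, 0),
        (5, PAIRED_END, 0),
        (6, SINGLE_END, 1),
        (10, SINGLE_END, 1),
        (20, PAIRED_END, 3),
        (20, SINGLE_END, 6),
        (100, PAIRED_END, 15),
        (100, SINGLE_END, 33),
    ],
)
def test_max_mismatches(length, mode, expected):
    assert max_mismatches(length, mode) == expected


@pytest.mark.parametrize("mode", [SINGLE_END, PAIRED_END])
def test_max_mismatches_monotone(mode):
    values = [max_mismatches(length, mode) for length in range(1, 400)]
    assert all(b >= a for a, b in zip(values, values[1:]))


def test_align_adapter_at_known_position():
    result = align_adapter_3prime("GGGGGAGATCGGAAGAGC", "AGATCGGAAGAGC")
    assert result.accepted
    assert result.offset == 5
    assert result.aligned_length == 13
    assert result.mismatches == 0


def test_align_adapter_no_positive_placement():
    assert not align_adapter_3prime("AAAAAAAAAA", "CCCCCCCCCC").accepted


def test_align_adapter_single_terminal_base():
    """A one-base terminal match is a valid (perfect) length-1 alignment."""
    read = "CCCCCCCCCG"
    result = align_adapter_3prime(read, "GATC")
    assert result.accepted
    assert result.offset == len(read) - 1
    assert result.aligned_length == 1


def test_score_identity_invariant():
    rng = np.random.default_rng(5)
    for _ in range(200):
        read = random_seq(rng, int(rng.integers(5, 40)), n_prob=0.05)
        adapter = random_seq(rng, int(rng.integers(1, 15)), n_prob=0.05)
        res = align_adapter_3prime(read, adapter)
        assert res.score == res.matches - res.mismatches
        assert res.mismatches + res.n_positions <= res.aligned_length


def test_oracle_equivalence_single_end():
    """Correlation-based enumeration equals brute force on >= 10^4 cases."""
    rng = np.random.default_rng(123)
    cfg = DEFAULT_ALIGNMENT
    for i in range(10_000):
        read = random_seq(rng, int(rng.integers(1, 31)), n_prob=0.05)
        adapter = random_seq(rng, int(rng.integers(1, 16)), n_prob=0.05)
        got = align_adapter_3prime(read, adapter, cfg)
        want = oracle_align_se(read, adapter, cfg)
        assert got == want, f"case {i}: {read} / {adapter}: {got} != {want}"


def test_oracle_equivalence_paired():
    rng = np.random.default_rng(321)
    cfg = DEFAULT_ALIGNMENT
    for i in range(1_500):
        r1 = random_seq(rng, int(rng.integers(1, 31)), n_prob=0.05)
        r2 = random_seq(rng, int(rng.integers(1, 31)), n_prob=0.05)
        a1 = random_seq(rng, int(rng.integers(1, 16)))
        a2 = random_seq(rng, int(rng.integers(1, 16)))
        got = align_pair(r1, r2, cfg, adapter1=a1, adapter2=a2)
        want = oracle_align_pair(r1, r2, a1, a2, cfg)
        assert got == want, f"case {i}: {got} != {want}"


def _contaminated_pair(rng, insert_len, read_len=75, a1=DEFAULT_ADAPTER1, a2=DEFAULT_ADAPTER2):
    insert = random_seq(rng, insert_len)
    pad1 = random_seq(rng, max(0, read_len - insert_len - len(a1)))
    pad2 = random_seq(rng, max(0, read_len - insert_len - len(a2)))
    read1 = (insert + a1 + pad1)[:read_len]
    read2 = (reverse_complement(insert) + a2 + pad2)[:read_len]
    return read1, read2


def test_align_pair_recovers_insert_length():
    rng = np.random.default_rng(7)
    read1, read2 = _contaminated_pair(rng, 50)
    res = align_pair(read1, read2, adapter1=DEFAULT_ADAPTER1, adapter2=DEFAULT_ADAPTER2)
    assert res.accepted
    assert inferred_insert_length(res, 75) == 50
    assert res.mismatches == 0


def test_align_pair_single_adapter_base():
    rng = np.random.default_rng(8)
    read1, read2 = _contaminated_pair(rng, 74)
    res = align_pair(read1, read2, adapter1=DEFAULT_ADAPTER1, adapter2=DEFAULT_ADAPTER2)
    assert res.accepted
    assert inferred_insert_length(res, 75) == 74


def test_align_pair_non_overlapping_rejected():
    rng = np.random.default_rng(9)
    fragment = random_seq(rng, 150)
    read1 = fragment[:75]
    read2 = reverse_complement(random_seq(rng, 75))
    res = align_pair(read1, read2, adapter1=DEFAULT_ADAPTER1, adapter2=DEFAULT_ADAPTER2)
    assert not res.accepted


def test_align_pair_symmetric_adapter_lengths():
    """Accepted placements imply equal adapter fragments on equal-length mates."""
    rng = np.random.default_rng(10)
    for insert_len in (5, 20, 40, 60, 74):
        read1, read2 = _contaminated_pair(rng, insert_len)
        res = align_pair(read1, read2, adapter1=DEFAULT_ADAPTER1, adapter2=DEFAULT_ADAPTER2)
        assert res.accepted
        insert = inferred_insert_length(res, 75)
        assert 75 - insert == 75 - insert  # same L_A on both mates by construction
        assert insert == insert_len


def test_shift_recovers_missing_5prime_bases():
    """Pairs whose mate 2 lost up to S leading bases still align at the
    correct biological offset (the truncated mate covers k fewer insert
    bases, so the implied insert shrinks by k)."""
    rng = np.random.default_rng(11)
    for k in (1, 2):
        read1, read2 = _contaminated_pair(rng, 50)
        read2_shifted = read2[k:]
        res = align_pair(
            read1, read2_shifted, adapter1=DEFAULT_ADAPTER1, adapter2=DEFAULT_ADAPTER2
        )
        assert res.accepted
        assert res.offset == -25
        assert inferred_insert_length(res, len(read2_shifted)) == 50 - k


def test_shifted_single_end_placement():
    """An adapter starting before the read start is found within the shift."""
    adapter = DEFAULT_ADAPTER1
    read = adapter[2:30]  # read is pure adapter missing its first 2 bases
    res = align_adapter_3prime(read, adapter)
    assert res.accepted
    assert res.offset == -2


def test_invalid_config():
    with pytest.raises(ValueError):
        AlignmentConfig(shift=-1)
    with pytest.raises(ValueError):
        AlignmentConfig(mismatch_rate_se=1.5)
    with pytest.raises(ValueError):
        AlignmentConfig(exact_cap=10, one_mismatch_cap=10)
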