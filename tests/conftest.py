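"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from seqclip.alignment import (
    AlignmentConfig,
    AlignmentResult,
    max_mismatches,
    reverse_complement,
    score_overlap,
    PAIRED_END,
    SINGLE_END,
)
from seqclip.fastq_io import Read

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    chars = [BASES[i] for i in rng.integers(0, 4, size=length)]
    if n_prob:
        for i in range(length):
            if rng.random() < n_prob:
                chars[i] = "N"
    return "".join(chars)


def make_read(seq: str, identifier: str = "r", quality: int = 30) -> Read:
    return Read(identifier, seq, np.full(len(seq), quality, dtype=np.int16))


def _oracle_overlap(s1: str, s2: str, offset: int) -> tuple[str, str]:
    """Aligned substrings of s1 and s2 when s2 starts at s1-coordinate offset."""
    start = max(0, offset)
    stop = max(start, min(len(s1), offset + len(s2)))
    return s1[start:stop], s2[start - offset : stop - offset]


def _oracle_select(
    candidates: list[tuple[int, str, str]],
    mode: str,
    cfg: AlignmentConfig,
) -> AlignmentResult:
    """Brute-force reference: score every placement with score_overlap and
    apply the documented selection rule (best score, then longest overlap,
    then smallest offset; accepted iff a placement passes the mismatch
    allowance and the best passing score is positive)."""
    scored = []
    for offset, a, b in candidates:
        if not a:
            continue
        score, mm, ns = score_overlap(a, b)
        passes = mm <= max_mismatches(len(a), mode, cfg)
        scored.append((offset, len(a), score, mm, ns, passes))
    passing = [c for c in scored if c[5]]
    pool = passing or scored
    if not pool:
        return AlignmentResult(0, 0, 0, 0, 0, False)
    best = max(pool, key=lambda c: (c[2], c[1], -c[0]))
    accepted = bool(passing) and best[2] > 0
    return AlignmentResult(best[0], best[1], best[2], best[3], best[4], accepted)


def oracle_align_se(read: str, adapter: str, cfg: AlignmentConfig) -> AlignmentResult:
    candidates = []
    for offset in range(-cfg.shift, len(read)):
        a, b = _oracle_overlap(read, adapter, offset)
        candidates.append((offset, a, b))
    return _oracle_select(candidates, SINGLE_END, cfg)


def oracle_align_pair(
    read1: str,
    read2: str,
    adapter1: str,
    adapter2: str,
    cfg: AlignmentConfig,
) -> AlignmentResult:
    """Two-stage brute force mirroring the documented pair contract:
    adapter-context pass first, then the plain fallback with its minimum
    aligned length."""
    s1 = reverse_complement(adapter2) + read1
    s2 = reverse_complement(read2) + adapter1
    pad = len(adapter2)
    candidates = []
    for d in range(-len(read2), len(read1)):
        a, b = _oracle_overlap(s1, s2, d + pad)
        candidates.append((d, a, b))
    padded = _oracle_select(candidates, PAIRED_END, cfg)
    if not adapter1 and not adapter2:
        return padded
    rc2 = reverse_complement(read2)
    candidates = []
    for d in range(-len(read2), len(read1)):
        a, b = _oracle_overlap(read1, rc2, d)
        if len(a) >= cfg.plain_min_overlap:
            candidates.append((d, a, b))
    plain = _oracle_select(candidates, PAIRED_END, cfg)
    key = lambda r: (r.score, r.aligned_length, -r.offset)
    if plain.accepted and (not padded.accepted or key(plain) > key(padded)):
        return plain
    return padded


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
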