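"""Adapter removal, end trimming and read filters.

Per read (or pair) the processing order is fixed: optional 5' adapter
trim, 3' adapter identification (single-end alignment against the adapter
or the paired alignment), optional pair collapse, N trimming, quality
trimming, and finally the length / N-count filters.  Adapter locations
are defined on raw read coordinates, so end trimming never runs before
adapter identification.  Every trimmed read is a contiguous substring of
its input with qualities sliced identically, and each step records its
provenance in a :class:`TrimAction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import (
    AlignmentConfig,
    AlignmentResult,
    DEFAULT_ALIGNMENT,
    align_adapter_3prime,
    align_pair,
    inferred_insert_length,
)
from .fastq_io import Read

# Widely used Illumina paired-end adapter sequences (adapter 1 is read
# into mate 1's 3' end, adapter 2 into mate 2's).
DEFAULT_ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTAGATCTCGGTGGTCGCCGTATCATT"

ADAPTER_3P = "adapter3p"
ADAPTER_5P = "adapter5p"
N_TRIM = "n_trim"
QUALITY_TRIM = "quality_trim"

TOO_SHORT = "too_short"
TOO_MANY_NS = "too_many_ns"


@dataclass
class TrimConfig:
    adapter1: str = DEFAULT_ADAPTER1
    adapter2: str = DEFAULT_ADAPTER2
    five_prime_adapter: str | None = None
    five_prime_slip: int = 2
    quality_threshold: int = 2
    trim_ns: bool = False
    trim_qualities: bool = False
    max_ns: int | None = None
    min_length: int = 15

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.five_prime_slip < 0:
            raise ValueError("five_prime_slip must be >= 0")


@dataclass
class TrimAction:
    """Provenance of what was removed from one read, and why."""

    bases_removed_5p: int = 0
    bases_removed_3p: int = 0
    reasons: set = field(default_factory=set)
    discarded: bool = False
    discard_reason: str | None = None

    @property
    def bases_removed(self) -> int:
        return self.bases_removed_5p + self.bases_removed_3p

    def merge(self, other: "TrimAction") -> "TrimAction":
        self.bases_removed_5p += other.bases_removed_5p
        self.bases_removed_3p += other.bases_removed_3p
        self.reasons |= other.reasons
        if other.discarded:
            self.discarded = True
            self.discard_reason = other.discard_reason
        return self


def trim_adapter_3prime_single(
    read: Read,
    cfg: TrimConfig,
    acfg: AlignmentConfig = DEFAULT_ALIGNMENT,
) -> tuple[Read, TrimAction]:
    """Remove a 3' adapter fragment located by single-end alignment.

    On acceptance the read is truncated at the adapter's inferred start;
    for shifted placements (adapter start before the read start) the whole
    read is removed.
    """
    action = TrimAction()
    result = align_adapter_3prime(read, cfg.adapter1, acfg)
    if result.accepted:
        cut = max(result.offset, 0)
        action.bases_removed_3p = len(read) - cut
        if action.bases_removed_3p:
            action.reasons.add(ADAPTER_3P)
        read = read.slice(0, cut)
    return read, action


def trim_adapter_pair(
    read1: Read,
    read2: Read,
    cfg: TrimConfig,
    acfg: AlignmentConfig = DEFAULT_ALIGNMENT,
) -> tuple[Read, Read, TrimAction, TrimAction, AlignmentResult]:
    """Symmetric 3' adapter removal driven by the paired alignment.

    If the accepted placement implies an insert shorter than a read, both
    mates are truncated to the insert length (adapter contamination is
    symmetric across the pair when no indels occur).  An accepted
    placement with insert >= read length means the mates merely overlap:
    nothing is trimmed, and the caller may collapse the pair instead.
    """
    a1, a2 = TrimAction(), TrimAction()
    result = align_pair(read1, read2, acfg, adapter1=cfg.adapter1, adapter2=cfg.adapter2)
    if result.accepted:
        insert_len = inferred_insert_length(result, len(read2))
        if insert_len < len(read1):
            a1.bases_removed_3p = len(read1) - insert_len
            a1.reasons.add(ADAPTER_3P)
            read1 = read1.slice(0, insert_len)
        if insert_len < len(read2):
            a2.bases_removed_3p = len(read2) - insert_len
            a2.reasons.add(ADAPTER_3P)
            read2 = read2.slice(0, insert_len)
    return read1, read2, a1, a2, result


def trim_adapter_5prime(read: Read, cfg: TrimConfig) -> tuple[Read, TrimAction]:
    """Remove a 5' adapter expected in near-full length at the read start.

    For each slip ``k`` in ``0 .. five_prime_slip`` the adapter minus its
    first ``k`` bases is compared against the read prefix of that length;
    the first (smallest-k) comparison with at most one mismatch wins, and
    slipped positions do not count as mismatches.  The whole remaining
    adapter must fit within the read.
    """
    action = TrimAction()
    adapter = cfg.five_prime_adapter
    if not adapter:
        return read, action
    for k in range(cfg.five_prime_slip + 1):
        fragment = adapter[k:]
        if not fragment or len(fragment) > len(read):
            continue
        mismatches = sum(
            1
            for a, b in zip(fragment, read.sequence)
            if a != b and a != "N" and b != "N"
        )
        if mismatches <= 1:
            action.bases_removed_5p = len(fragment)
            action.reasons.add(ADAPTER_5P)
            return read.slice(len(fragment), len(read)), action
    return read, action


def trim_ns(read: Read) -> tuple[Read, TrimAction]:
    """Remove maximal runs of N from both ends; interior Ns are kept."""
    action = TrimAction()
    seq = read.sequence
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    stop = len(seq)
    while stop > start and seq[stop - 1] == "N":
        stop -= 1
    if start or stop < len(seq):
        action.bases_removed_5p = start
        action.bases_removed_3p = len(seq) - stop
        action.reasons.add(N_TRIM)
        read = read.slice(start, stop)
    return read, action


def trim_low_quality(read: Read, threshold: int = 2) -> tuple[Read, TrimAction]:
    """Remove terminal runs whose quality does not exceed ``threshold``."""
    action = TrimAction()
    q = read.qualities
    start = 0
    while start < q.size and q[start] <= threshold:
        start += 1
    stop = q.size
    while stop > start and q[stop - 1] <= threshold:
        stop -= 1
    if start or stop < q.size:
        action.bases_removed_5p = start
        action.bases_removed_3p = int(q.size - stop)
        action.reasons.add(QUALITY_TRIM)
        read = read.slice(start, stop)
    return read, action


def apply_filters(read: Read, cfg: TrimConfig) -> TrimAction:
    """Final keep/discard decision on an already-trimmed read."""
    action = TrimAction()
    if cfg.max_ns is not None and read.sequence.count("N") > cfg.max_ns:
        action.discarded = True
        action.discard_reason = TOO_MANY_NS
    elif len(read) < cfg.min_length:
        action.discarded = True
        action.discard_reason = TOO_SHORT
    return action


def process_read(
    read: Read,
    cfg: TrimConfig,
    acfg: AlignmentConfig = DEFAULT_ALIGNMENT,
    skip_adapter: bool = False,
) -> tuple[Read, TrimAction]:
    """Run the full single-read trimming chain in canonical order."""
    total = TrimAction()
    if cfg.five_prime_adapter:
        read, act = trim_adapter_5prime(read, cfg)
        total.merge(act)
    if not skip_adapter:
        read, act = trim_adapter_3prime_single(read, cfg, acfg)
        total.merge(act)
    read, total = finish_read(read, cfg, total)
    return read, total


def finish_read(
    read: Read, cfg: TrimConfig, total: TrimAction
) -> tuple[Read, TrimAction]:
    """Shared tail of the chain: N trim, quality trim, filters."""
    if cfg.trim_ns:
        read, act = trim_ns(read)
        total.merge(act)
    if cfg.trim_qualities:
        read, act = trim_low_quality(read, cfg.quality_threshold)
        total.merge(act)
    total.merge(apply_filters(read, cfg))
    return read, total
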