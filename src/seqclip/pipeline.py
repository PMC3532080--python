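"""End-to-end orchestration of per-read / per-pair processing.

Processing is streaming: one read or pair is held in memory at a time and
written to its destination before the next is parsed, so memory use does
not grow with input size.  Every run produces a :class:`RunSummary` whose
counts satisfy the accounting identity

    reads in == trimmed out + singletons + 2 * collapsed pairs + discarded

(collapsed pairs consume two input reads and emit one consensus read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alignment import AlignmentConfig, DEFAULT_ALIGNMENT, inferred_insert_length
from .collapser import CollapseConfig, DEFAULT_COLLAPSE, collapse_pair
from .fastq_io import OutputRouter, Read
from .trimmer import (
    TrimAction,
    TrimConfig,
    finish_read,
    process_read,
    trim_adapter_5prime,
    trim_adapter_pair,
)


@dataclass
class RunSummary:
    total_reads_in: int = 0
    total_reads_out: int = 0
    reads_trimmed_adapter: int = 0
    collapsed_pairs: int = 0
    singletons: int = 0
    discarded: int = 0
    discard_reasons: dict = field(default_factory=dict)
    destination_counts: dict = field(default_factory=dict)

    def note_discard(self, reason: str | None) -> None:
        self.discarded += 1
        key = reason or "unknown"
        self.discard_reasons[key] = self.discard_reasons.get(key, 0) + 1

    def render(self) -> str:
        lines = [
            f"total_reads_in: {self.total_reads_in}",
            f"total_reads_out: {self.total_reads_out}",
            f"reads_trimmed_adapter: {self.reads_trimmed_adapter}",
            f"collapsed_pairs: {self.collapsed_pairs}",
            f"singletons: {self.singletons}",
            f"discarded: {self.discarded}",
        ]
        for reason in sorted(self.discard_reasons):
            lines.append(f"discarded_{reason}: {self.discard_reasons[reason]}")
        for dest in sorted(self.destination_counts):
            lines.append(f"written_{dest}: {self.destination_counts[dest]}")
        return "\n".join(lines) + "\n"


def process_single_end(
    reads: Iterable[Read],
    cfg: TrimConfig,
    acfg: AlignmentConfig,
    router: OutputRouter,
) -> RunSummary:
    """Trim and filter single-end reads; kept reads go to ``mate1``."""
    summary = RunSummary()
    for read in reads:
        summary.total_reads_in += 1
        trimmed, action = process_read(read, cfg, acfg)
        if "adapter3p" in action.reasons or "adapter5p" in action.reasons:
            summary.reads_trimmed_adapter += 1
        if action.discarded:
            router.route(trimmed, "discarded")
            summary.note_discard(action.discard_reason)
        else:
            router.route(trimmed, "mate1")
            summary.total_reads_out += 1
    summary.destination_counts = dict(router.counts)
    return summary


def _iter_pairs(
    reads1: Iterator[Read], reads2: Iterator[Read]
) -> Iterator[tuple[Read, Read]]:
    n1 = n2 = 0
    while True:
        r1 = next(reads1, None)
        r2 = next(reads2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            n1 += r1 is not None
            n2 += r2 is not None
            # drain to report counts
            n1 += sum(1 for _ in reads1)
            n2 += sum(1 for _ in reads2)
            raise ValueError(
                f"paired inputs differ in record count: file 1 has {n1} "
                f"extra-or-missing vs file 2 {n2} (after the common prefix)"
            )
        n1 += 1
        n2 += 1
        yield r1, r2


def process_paired_end(
    reads1: Iterator[Read],
    reads2: Iterator[Read],
    cfg: TrimConfig,
    acfg: AlignmentConfig,
    router: OutputRouter,
    collapse: bool = False,
    ccfg: CollapseConfig = DEFAULT_COLLAPSE,
) -> RunSummary:
    """Process read pairs: align, trim symmetrically, optionally collapse.

    Surviving pairs are written to ``mate1``/``mate2`` in input order; if
    exactly one mate survives it goes to ``singleton``; collapsed pairs
    emit a single consensus read to ``collapsed``.
    """
    summary = RunSummary()
    for raw1, raw2 in _iter_pairs(iter(reads1), iter(reads2)):
        summary.total_reads_in += 2
        act1, act2 = TrimAction(), TrimAction()
        r1, r2 = raw1, raw2
        if cfg.five_prime_adapter:
            r1, a = trim_adapter_5prime(r1, cfg)
            act1.merge(a)
            r2, a = trim_adapter_5prime(r2, cfg)
            act2.merge(a)
        r1, r2, a1, a2, placement = trim_adapter_pair(r1, r2, cfg, acfg)
        act1.merge(a1)
        act2.merge(a2)
        for act in (act1, act2):
            if "adapter3p" in act.reasons or "adapter5p" in act.reasons:
                summary.reads_trimmed_adapter += 1
        if collapse and placement.accepted:
            # Collapse from the raw (un-truncated) mates: the consensus
            # spans the full insert including any singly-covered flanks.
            # A consensus that would fail the filters is treated as a
            # refusal and the pair falls back to ordinary trimming, so the
            # destination accounting stays exact.
            merged = collapse_pair(raw1, raw2, placement, ccfg)
            if merged is not None:
                out, act = finish_read(merged.read, cfg, TrimAction())
                if not act.discarded:
                    router.route(out, "collapsed")
                    summary.total_reads_out += 1
                    summary.collapsed_pairs += 1
                    continue
        r1, act1 = finish_read(r1, cfg, act1)
        r2, act2 = finish_read(r2, cfg, act2)
        keep1, keep2 = not act1.discarded, not act2.discarded
        if keep1 and keep2:
            router.route(r1, "mate1")
            router.route(r2, "mate2")
            summary.total_reads_out += 2
        elif keep1 or keep2:
            survivor = r1 if keep1 else r2
            lost, lost_act = (r2, act2) if keep1 else (r1, act1)
            router.route(survivor, "singleton")
            router.route(lost, "discarded")
            summary.singletons += 1
            summary.total_reads_out += 1
            summary.note_discard(lost_act.discard_reason)
        else:
            router.route(r1, "discarded")
            router.route(r2, "discarded")
            summary.note_discard(act1.discard_reason)
            summary.note_discard(act2.discard_reason)
    summary.destination_counts = dict(router.counts)
    return summary


def summarize(summary: RunSummary) -> str:
    """Human- and machine-readable ``key: value`` rendering of a run."""
    return summary.render()
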