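"""Merging overlapping read pairs with quality re-estimation.

The overlap between two mates is treated as a position-specific scoring
matrix: each observed base with Phred score Q defines a distribution over
{A, C, G, T} assigning probability ``1 - Pe`` to the called base and
``Pe / 3`` to each alternative, with ``Pe = 10^(-Q/10)``.  The two
per-position distributions are combined as a renormalised product (a
likelihood combination), the consensus base is the argmax, and its
posterior error ``1 - p_max`` is translated back to a Phred score.

Design choices where the combination rule leaves freedom:

* An observed N contributes the uniform distribution (the multiplicative
  identity), so pairing any call with an N returns the call unchanged.
* Exact ties between the top two bases (e.g. equal qualities, different
  bases) emit N with quality 0 — there is no principled basis to prefer
  either observation.
* Re-estimated qualities are capped (default 41): two agreeing Q40 bases
  would otherwise imply a score near 80, outside the range downstream
  tools expect.
* Rounding is half-up to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentResult, inferred_insert_length, reverse_complement
from .fastq_io import Read

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Relative tolerance treating two posterior probabilities as tied.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class CollapseConfig:
    """Parameters of pair merging.

    ``min_overlap`` is the number of doubly-observed (re-estimated)
    positions required before a pair may be merged; ``max_quality`` caps
    the re-estimated Phred scores; ``id_prefix`` marks merged reads.
    """

    min_overlap: int = 11
    max_quality: int = 41
    id_prefix: str = "M_"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


DEFAULT_COLLAPSE = CollapseConfig()


def phred_to_error(q: float) -> float:
    """Error probability for a Phred score: ``Pe = 10^(-Q/10)``."""
    if q < 0:
        raise ValueError("Phred score must be non-negative")
    return 10.0 ** (-q / 10.0)


def base_distribution(base: str, q: float) -> np.ndarray:
    """Probability vector over (A, C, G, T) implied by one observation.

    The called base receives ``P1 = 1 - Pe`` and each of the other three
    bases ``P2 = Pe / 3``.  An N carries no information and yields the
    uniform distribution.
    """
    if base == "N":
        return np.full(4, 0.25)
    pe = phred_to_error(q)
    dist = np.full(4, pe / 3.0)
    dist[_BASE_INDEX[base]] = 1.0 - pe
    return dist


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def combined_distribution(
    base1: str, q1: float, base2: str, q2: float
) -> np.ndarray | None:
    """Renormalised product of the two observations' distributions.

    Returns the posterior probability vector over (A, C, G, T), or
    ``None`` if the product places zero mass everywhere (a numerical
    guard; unreachable for valid Phred inputs).
    """
    combined = base_distribution(base1, q1) * base_distribution(base2, q2)
    total = combined.sum()
    if total <= 0.0:
        return None
    return combined / total


def combine_position(
    base1: str,
    q1: float,
    base2: str,
    q2: float,
    cfg: CollapseConfig = DEFAULT_COLLAPSE,
) -> tuple[str, int]:
    """Consensus base and re-estimated Phred score for one overlap position."""
    combined = combined_distribution(base1, q1, base2, q2)
    if combined is None:
        return "N", 0
    order = np.argsort(combined)
    p_max = combined[order[-1]]
    runner_up = combined[order[-2]]
    if p_max - runner_up <= _TIE_RTOL * p_max:
        return "N", 0
    p_err = 1.0 - p_max
    if p_err <= 0.0:
        return _BASES[order[-1]], cfg.max_quality
    q = _round_half_up(-10.0 * math.log10(p_err))
    return _BASES[order[-1]], min(q, cfg.max_quality)


@dataclass
class CollapsedRead:
    read: Read
    overlap_length: int


def collapse_pair(
    read1: Read,
    read2: Read,
    placement: AlignmentResult,
    cfg: CollapseConfig = DEFAULT_COLLAPSE,
) -> CollapsedRead | None:
    """Merge an aligned pair into one consensus read spanning the insert.

    ``placement`` must be an accepted paired alignment of the *raw* reads
    (read 2 not yet reverse-complemented).  Returns ``None`` (a refusal,
    a perfectly normal outcome) when fewer than ``cfg.min_overlap``
    positions are observed by both mates; the caller should then emit the
    pair as ordinary trimmed reads.

    The output has exactly the inferred insert length: flanking positions
    seen by a single mate are copied verbatim, doubly-observed positions
    go through :func:`combine_position`, and positions read past the
    insert on either mate (adapter bases) are dropped.
    """
    if not placement.accepted:
        return None
    insert_len = inferred_insert_length(placement, len(read2))
    offset = placement.offset
    seq2 = reverse_complement(read2.sequence)
    qual2 = read2.qualities[::-1]

    lo = max(0, offset)               # first doubly-observed insert position
    hi = min(len(read1), insert_len)  # one past the last
    overlap_length = max(0, hi - lo)
    if overlap_length < cfg.min_overlap:
        return None

    seq_parts: list[str] = [read1.sequence[:lo]]
    quals = np.empty(insert_len, dtype=np.int16)
    quals[:lo] = read1.qualities[:lo]
    mid_seq = []
    for i in range(lo, hi):
        base, q = combine_position(
            read1.sequence[i],
            int(read1.qualities[i]),
            seq2[i - offset],
            int(qual2[i - offset]),
            cfg,
        )
        mid_seq.append(base)
        quals[i] = q
    seq_parts.append("".join(mid_seq))
    seq_parts.append(seq2[hi - offset : insert_len - offset])
    quals[hi:] = qual2[hi - offset : insert_len - offset]
    merged = Read(
        cfg.id_prefix + read1.identifier, "".join(seq_parts), quals
    )
    return CollapsedRead(read=merged, overlap_length=overlap_length)
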