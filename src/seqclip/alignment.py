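"""Ungapped semiglobal alignment for adapter detection.

Two alignment problems are solved here:

* **Single-end**: the 3' end of a read against the 5' end of a known
  adapter sequence.  Every placement of the adapter's first base at read
  positions ``0 .. len(read)-1`` is evaluated, plus ``S`` extra placements
  where the adapter start precedes the read start (the *shift*,
  compensating for bases missing from the read's 5' end; adapter bases
  falling before the read are ignored because they were never sequenced).

* **Paired-end**: read 1 against the reverse complement of read 2.  The
  two strings are extended with their expected adapter context — the
  reverse complement of adapter 2 is prepended to read 1, and adapter 1 is
  appended to the reverse complement of read 2 — so that at the true
  placement the adapter fragments on *both* mates align against the known
  adapter sequences.  This makes the paired mode sensitive down to a
  single contaminating adapter base while keeping chance acceptance of
  clean pairs vanishingly rare: a placement implying contamination always
  spans the full read plus the implied adapter evidence, so a spurious
  match would have to survive the mismatch allowance over ~75+ positions.
  Because the context is attached rigidly, it misaligns for reads that
  lost bases at their 5' end (the context junction shifts with the read);
  a plain read-vs-read pass therefore serves as a fallback whenever the
  padded pass accepts nothing.  To keep the fallback from accepting
  chance micro-overlaps between unrelated reads it requires a minimum
  aligned length (``plain_min_overlap``).

Scoring is +1 per matching base, -1 per mismatching base and 0 wherever
either base is N (N positions count toward the aligned length but never
toward the mismatch tally).  Gaps are not modelled: indels are rare in
Illumina data compared to substitutions.

The candidate placements are scored with cross-correlations of one-hot
base indicators, which evaluates every diagonal of the (banded) dynamic
programming matrix in a handful of vectorised passes.  The normative
contract is equivalence with direct enumeration of all offsets under the
scoring scheme above; the test suite checks this against a brute-force
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fastq_io import Read

# Base codes: A=0, C=1, G=2, T=3, N=4.
N_CODE = 4
_ENCODE_TABLE = bytearray([N_CODE]) * 256
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE_TABLE[_b] = _i
_ENCODE_TABLE = bytes(_ENCODE_TABLE)
_DECODE_TABLE = bytes.maketrans(bytes(range(5)), b"ACGTN")
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

SINGLE_END = "single-end"
PAIRED_END = "paired-end"


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 code array (unknown chars -> N)."""
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(_DECODE_TABLE).decode("ascii")


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def reverse_complement(seq: str) -> str:
    return decode(reverse_complement_codes(encode(seq)))


@dataclass(frozen=True)
class AlignmentConfig:
    """Scoring and acceptance parameters.

    ``shift`` (S) is the number of placements past the default band, i.e.
    how far one sequence may slide toward the 3' end to recover reads
    missing bases at their 5' end.  Short alignments are held to stricter
    standards than the global mismatch fraction: up to ``exact_cap``
    aligned bases must match perfectly, and up to ``one_mismatch_cap``
    bases allow a single mismatch.  Longer alignments allow
    ``floor(rate * length)`` mismatches, with mode-specific rates.
    """

    shift: int = 2
    mismatch_rate_se: float = 0.33
    mismatch_rate_pe: float = 0.15
    exact_cap: int = 5
    one_mismatch_cap: int = 10
    plain_min_overlap: int = 20

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        for rate in (self.mismatch_rate_se, self.mismatch_rate_pe):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("mismatch rates must lie in [0, 1]")
        if self.exact_cap >= self.one_mismatch_cap:
            raise ValueError("exact_cap must be below one_mismatch_cap")

    def rate(self, mode: str) -> float:
        if mode == SINGLE_END:
            return self.mismatch_rate_se
        if mode == PAIRED_END:
            return self.mismatch_rate_pe
        raise ValueError(f"unknown mode {mode!r}")


DEFAULT_ALIGNMENT = AlignmentConfig()


@dataclass
class AlignmentResult:
    """Best ungapped placement of sequence B relative to sequence A.

    ``offset`` is the position of B's first base relative to A's first
    base, in *read* coordinates (for the paired mode, A is read 1 and B is
    the reverse complement of read 2, regardless of the adapter padding
    used internally).  Negative offsets encode the shift extension.
    The bookkeeping identity ``score == matches - mismatches`` with
    ``matches = aligned_length - mismatches - n_positions`` always holds.
    """

    offset: int
    aligned_length: int
    score: int
    mismatches: int
    n_positions: int
    accepted: bool

    @property
    def matches(self) -> int:
        return self.aligned_length - self.mismatches - self.n_positions


def score_overlap(a: str, b: str) -> tuple[int, int, int]:
    """Score two equal-length strings position by position.

    Returns ``(score, mismatches, n_positions)``: equal non-N bases score
    +1; differing non-N bases score -1 and count one mismatch; positions
    where either base is N score 0 and count one n_position.
    """
    if len(a) != len(b) or not a:
        raise ValueError("score_overlap requires equal non-zero lengths")
    score = mismatches = n_positions = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            n_positions += 1
        elif x == y:
            score += 1
        else:
            score -= 1
            mismatches += 1
    return score, mismatches, n_positions


def max_mismatches(aligned_length: int, mode: str, cfg: AlignmentConfig = DEFAULT_ALIGNMENT) -> int:
    """Mismatch allowance for an alignment of the given length."""
    if aligned_length < 1:
        raise ValueError("aligned_length must be >= 1")
    if aligned_length <= cfg.exact_cap:
        return 0
    if aligned_length <= cfg.one_mismatch_cap:
        return 1
    # 1e-9 guards against representation error in rate * length.
    return int(np.floor(cfg.rate(mode) * aligned_length + 1e-9))


def _overlap_lengths(m: int, n: int) -> np.ndarray:
    """Geometric overlap length for every offset o in [-(n-1), m-1]."""
    offsets = np.arange(-(n - 1), m)
    return np.minimum(m, offsets + n) - np.maximum(0, offsets)


def _enumerate_offsets(s1: np.ndarray, s2: np.ndarray) -> tuple[np.ndarray, ...]:
    """Score every relative placement of s2 against s1.

    Returns (offsets, lengths, scores, mismatches, n_positions), all
    integer arrays indexed by candidate placement, computed with one-hot
    cross-correlations (one pass per base channel plus one for the
    non-N indicators).
    """
    m, n = len(s1), len(s2)
    matches = np.zeros(m + n - 1)
    for code in range(4):
        matches += np.correlate(
            (s1 == code).astype(np.float64), (s2 == code).astype(np.float64), "full"
        )
    non_n = np.correlate(
        (s1 != N_CODE).astype(np.float64), (s2 != N_CODE).astype(np.float64), "full"
    )
    offsets = np.arange(-(n - 1), m)
    lengths = _overlap_lengths(m, n)
    matches = np.rint(matches).astype(np.int64)
    non_n = np.rint(non_n).astype(np.int64)
    mismatches = non_n - matches
    n_positions = lengths - non_n
    scores = matches - mismatches
    return offsets, lengths, scores, mismatches, n_positions


def _select_best(
    offsets: np.ndarray,
    lengths: np.ndarray,
    scores: np.ndarray,
    mismatches: np.ndarray,
    n_positions: np.ndarray,
    mode: str,
    cfg: AlignmentConfig,
    mask: np.ndarray,
) -> AlignmentResult:
    """Pick the best placement among those passing the mismatch allowance.

    Preference order: higher score, then longer aligned length (equal
    score over a longer overlap minimises residual adapter), then smaller
    offset (more conservative toward removing contamination).  The result
    is accepted only if a passing placement exists and its score is
    strictly positive — a non-positive score means mismatches plus Ns
    outweigh matches, i.e. no evidence.
    """
    usable = mask & (lengths >= 1)
    rate = cfg.rate(mode)
    allowance = np.where(
        lengths <= cfg.exact_cap,
        0,
        np.where(
            lengths <= cfg.one_mismatch_cap,
            1,
            np.floor(rate * lengths + 1e-9).astype(np.int64),
        ),
    )
    passing = usable & (mismatches <= allowance)
    pool = passing if passing.any() else usable
    idx = np.flatnonzero(pool)
    if idx.size == 0:
        return AlignmentResult(0, 0, 0, 0, 0, False)
    order = np.lexsort((-offsets[idx], lengths[idx], scores[idx]))
    best = idx[order[-1]]
    accepted = bool(passing.any() and scores[best] > 0)
    return AlignmentResult(
        offset=int(offsets[best]),
        aligned_length=int(lengths[best]),
        score=int(scores[best]),
        mismatches=int(mismatches[best]),
        n_positions=int(n_positions[best]),
        accepted=accepted,
    )


def align_adapter_3prime(
    read: Read | str,
    adapter: str,
    cfg: AlignmentConfig = DEFAULT_ALIGNMENT,
) -> AlignmentResult:
    """Locate the adapter's 5' end within the 3' end of a single read.

    Candidate placements put the adapter's first base at read positions
    ``-S .. len(read)-1``; for negative placements the adapter bases that
    fall before the read start are ignored.  On acceptance the read should
    be truncated at ``max(offset, 0)``.
    """
    seq = read.sequence if isinstance(read, Read) else read
    if not seq or not adapter:
        raise ValueError("read and adapter must be non-empty")
    s1 = encode(seq)
    s2 = encode(adapter)
    offsets, lengths, scores, mismatches, n_positions = _enumerate_offsets(s1, s2)
    mask = offsets >= -cfg.shift
    return _select_best(
        offsets, lengths, scores, mismatches, n_positions, SINGLE_END, cfg, mask
    )


def align_pair(
    read1: Read | str,
    read2: Read | str,
    cfg: AlignmentConfig = DEFAULT_ALIGNMENT,
    adapter1: str = "",
    adapter2: str = "",
) -> AlignmentResult:
    """Align read 1 against the reverse complement of read 2.

    ``adapter1``/``adapter2`` provide the expected adapter context: the
    reverse complement of adapter 2 is prepended to read 1 and adapter 1
    is appended to the reverse complement of read 2 before enumeration.
    An accepted placement then pins down the insert length
    ``L_I = len(read2) + offset`` and hence the adapter fragment length
    ``L_A = len(read) - L_I`` on both mates simultaneously.

    ``offset`` in the result is expressed in read coordinates (reverse-
    complemented read 2 relative to read 1); the adapter padding is an
    internal device and contributes to score/length bookkeeping only.
    Candidate placements range from the reads fully overlapping down to
    an implied insert length of zero (pure adapter on both mates).

    A second, plain read-vs-read pass (no padding) covers reads that
    lost bases from their 5' end, which displaces the rigid context
    junction and wrecks the padded score at the true placement.  The
    plain pass accepts only placements at least ``cfg.plain_min_overlap``
    bases long — unrelated reads routinely share chance micro-overlaps —
    and the better accepted result of the two passes (by score, then
    aligned length, then smaller offset) is returned.
    """
    seq1 = read1.sequence if isinstance(read1, Read) else read1
    seq2 = read2.sequence if isinstance(read2, Read) else read2
    if not seq1 or not seq2:
        raise ValueError("both reads must be non-empty")
    pad_left = encode(reverse_complement(adapter2)) if adapter2 else np.empty(0, np.uint8)
    pad_right = encode(adapter1) if adapter1 else np.empty(0, np.uint8)
    rc2 = reverse_complement_codes(encode(seq2))
    s1 = np.concatenate([pad_left, encode(seq1)])
    s2 = np.concatenate([rc2, pad_right])
    offsets, lengths, scores, mismatches, n_positions = _enumerate_offsets(s1, s2)
    # Convert padded-string offsets to read coordinates.  Placements down
    # to offset -len(read2) are admitted: that extreme encodes an insert
    # of length zero (pure adapter on both mates), which is detectable
    # purely from the adapter context.
    read_offsets = offsets - len(pad_left)
    mask = (read_offsets >= -len(seq2)) & (read_offsets <= len(seq1) - 1)
    padded = _select_best(
        read_offsets, lengths, scores, mismatches, n_positions, PAIRED_END, cfg, mask
    )
    if not len(pad_left) and not len(pad_right):
        return padded
    offsets, lengths, scores, mismatches, n_positions = _enumerate_offsets(
        encode(seq1), rc2
    )
    mask = lengths >= cfg.plain_min_overlap
    plain = _select_best(
        offsets, lengths, scores, mismatches, n_positions, PAIRED_END, cfg, mask
    )
    if plain.accepted and (not padded.accepted or _result_key(plain) > _result_key(padded)):
        return plain
    return padded


def _result_key(result: AlignmentResult) -> tuple[int, int, int]:
    """Preference order between accepted placements."""
    return (result.score, result.aligned_length, -result.offset)


def inferred_insert_length(result: AlignmentResult, read2_length: int) -> int:
    """Insert length implied by an accepted paired placement."""
    return read2_length + result.offset
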