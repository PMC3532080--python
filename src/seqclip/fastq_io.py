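"""FASTQ reading, writing and output routing.

Only strict 4-line FASTQ records are accepted (one line each for header,
sequence, separator and qualities).  Wrapped/multi-line FASTQ is rejected:
it does not occur in modern sequencer output and rejecting it keeps the
parser trivially verifiable.  Both Phred+33 and Phred+64 ASCII encodings
are supported, and plain or gzip-compressed streams are detected by
sniffing the two gzip magic bytes.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

#: Characters a sequence may contain after ingest normalization.
VALID_BASES = frozenset("ACGTN")

# Highest ASCII code emitted/accepted is '~' (126); this bounds the
# encodable Phred range per offset.
_MAX_ASCII = 126

DESTINATIONS = ("mate1", "mate2", "singleton", "collapsed", "discarded")


class FastqParseError(ValueError):
    """Raised for truncated records, length mismatches or bad quality bytes."""


@dataclass(frozen=True)
class QualityEncoding:
    """ASCII offset used to encode Phred scores (33 by default, or 64)."""

    offset: int = 33

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"quality offset must be 33 or 64, got {self.offset}")

    @property
    def max_quality(self) -> int:
        return _MAX_ASCII - self.offset


PHRED33 = QualityEncoding(33)
PHRED64 = QualityEncoding(64)


@dataclass
class Read:
    """A single FASTQ record.

    ``qualities`` is an integer array of Phred scores, one per base.
    The sequence is uppercase over the alphabet {A, C, G, T, N}.
    """

    identifier: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != self.qualities.size:
            raise ValueError(
                f"read {self.identifier!r}: sequence length {len(self.sequence)} "
                f"!= quality length {self.qualities.size}"
            )
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 93
        ):
            raise ValueError(f"read {self.identifier!r}: Phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Read):
            return NotImplemented
        return (
            self.identifier == other.identifier
            and self.sequence == other.sequence
            and np.array_equal(self.qualities, other.qualities)
        )

    def slice(self, start: int, stop: int) -> "Read":
        """Contiguous sub-read with qualities sliced identically."""
        return Read(self.identifier, self.sequence[start:stop], self.qualities[start:stop])


def decode_quality(char: str, enc: QualityEncoding = PHRED33) -> int:
    """Decode one quality character to an integer Phred score."""
    code = ord(char)
    if code < enc.offset:
        raise FastqParseError(
            f"quality character {char!r} (ASCII {code}) below Phred+{enc.offset} offset"
        )
    return code - enc.offset


def encode_quality(q: int, enc: QualityEncoding = PHRED33) -> str:
    """Encode an integer Phred score as one ASCII character."""
    if q < 0 or q > enc.max_quality:
        raise ValueError(
            f"Phred score {q} not encodable with offset {enc.offset} "
            f"(range 0..{enc.max_quality})"
        )
    return chr(q + enc.offset)


# Translate anything that is not an uppercase ACGTN into 'N'.
_NORMALIZE = {}
for _i in range(256):
    _ch = chr(_i)
    if _ch.upper() in VALID_BASES:
        _NORMALIZE[_i] = _ch.upper()
    else:
        _NORMALIZE[_i] = "N"
_NORMALIZE = str.maketrans(_NORMALIZE)


def open_maybe_gzip(path: str, mode: str = "rt") -> IO:
    """Open a path as text, transparently handling gzip.

    Reading sniffs the two magic bytes; writing gzips iff the filename
    ends in ``.gz``.
    """
    if "r" in mode:
        raw = open(path, "rb")
        magic = raw.read(2)
        raw.seek(0)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(raw, "rb"))
        return io.TextIOWrapper(raw)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode if "b" in mode else mode + "t")
    return open(path, mode)


def read_fastq(
    source: IO | str,
    enc: QualityEncoding = PHRED33,
) -> Iterator[Read]:
    """Yield :class:`Read` records from a 4-line FASTQ stream or path.

    Lowercase bases are uppercased; characters outside {A,C,G,T,N} are
    replaced by N with a logged warning.  Truncated records and
    sequence/quality length mismatches raise :class:`FastqParseError`
    naming the record ordinal.
    """
    handle = open_maybe_gzip(source) if isinstance(source, str) else source
    close = isinstance(source, str)
    try:
        ordinal = 0
        while True:
            header = handle.readline()
            if not header:
                return
            ordinal += 1
            seq_line = handle.readline()
            sep = handle.readline()
            qual_line = handle.readline()
            if not qual_line:
                raise FastqParseError(f"record {ordinal}: truncated FASTQ record")
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(
                    f"record {ordinal}: header does not start with '@': {header!r}"
                )
            if not sep.startswith("+"):
                raise FastqParseError(
                    f"record {ordinal}: separator line does not start with '+' "
                    "(multi-line FASTQ is not supported)"
                )
            identifier = header[1:]
            raw_seq = seq_line.rstrip("\n")
            qual_str = qual_line.rstrip("\n")
            if len(raw_seq) != len(qual_str):
                raise FastqParseError(
                    f"record {ordinal} ({identifier!r}): sequence length "
                    f"{len(raw_seq)} != quality length {len(qual_str)}"
                )
            sequence = raw_seq.translate(_NORMALIZE)
            n_replaced = sum(
                1 for a, b in zip(raw_seq, sequence) if a.upper() != b
            )
            if n_replaced:
                logger.warning(
                    "record %d (%s): replaced %d non-ACGTN character(s) with N",
                    ordinal, identifier, n_replaced,
                )
            quals = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - enc.offset
            if quals.size and quals.min() < 0:
                raise FastqParseError(
                    f"record {ordinal} ({identifier!r}): quality character below "
                    f"Phred+{enc.offset} offset at position {int(quals.argmin())}"
                )
            yield Read(identifier, sequence, quals)
    finally:
        if close:
            handle.close()


def write_fastq(
    reads: Iterable[Read],
    sink: IO | str,
    enc: QualityEncoding = PHRED33,
) -> None:
    """Write reads as 4-line FASTQ records; inverse of :func:`read_fastq`."""
    handle = open_maybe_gzip(sink, "wt") if isinstance(sink, str) else sink
    close = isinstance(sink, str)
    try:
        for read in reads:
            handle.write(format_record(read, enc))
    finally:
        if close:
            handle.close()


def format_record(read: Read, enc: QualityEncoding = PHRED33) -> str:
    quals = read.qualities
    if quals.size and quals.max() > enc.max_quality:
        raise ValueError(
            f"read {read.identifier!r}: quality {int(quals.max())} exceeds the "
            f"encodable Phred+{enc.offset} range (max {enc.max_quality})"
        )
    qual_str = (quals + enc.offset).astype(np.uint8).tobytes().decode("ascii")
    return f"@{read.identifier}\n{read.sequence}\n+\n{qual_str}\n"


@dataclass
class OutputRouter:
    """Routes each processed read to exactly one destination sink.

    Destinations are ``mate1``, ``mate2``, ``singleton``, ``collapsed`` and
    ``discarded``.  Single-end runs use only ``mate1`` (the trimmed-read
    output) and ``discarded``.  Pair ordering is the caller's concern: the
    pipeline writes mate1/mate2 records strictly in input pair order.
    """

    sinks: dict
    encoding: QualityEncoding = PHRED33
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dest in self.sinks:
            if dest not in DESTINATIONS:
                raise ValueError(f"unknown destination {dest!r}")
        self.counts = {dest: 0 for dest in DESTINATIONS}

    def route(self, read: Read, destination: str) -> None:
        if destination not in self.sinks:
            raise ValueError(f"no sink configured for destination {destination!r}")
        self.sinks[destination].write(format_record(read, self.encoding))
        self.counts[destination] += 1

    def close(self) -> None:
        for sink in self.sinks.values():
            sink.close()
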