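"""Truth-annotated read-pair simulation and trimming benchmark.

The simulator emulates a 75-nt paired-end Illumina run.  For each pair an
insert length ``L_I`` is drawn uniformly on a closed interval (default
``[0, 200]``) and compared with the read length ``L_R``:

* ``L_I >= 2 * L_R`` — the mates neither overlap nor carry adapter; the
  base pair is emitted unchanged.
* ``L_R <= L_I < 2 * L_R`` — the mates overlap in their 3' ends but carry
  no adapter.  The overlapping subsequence is taken from read 1,
  reverse-complemented, written into the 3' end of read 2, and the newly
  written bases are mutated according to read 2's quality scores.
* ``L_I < L_R`` — both mates carry ``L_A = L_R - L_I`` adapter bases.
  Read 2 becomes the reverse complement of read 1's first ``L_I`` bases,
  adapter sequence is appended to both mates (two different adapters),
  and both full reads are then mutated according to their qualities.
  If the insert plus the adapter does not fill the read, the remainder is
  random off-template bases (a sequencer reading past the library
  construct); those bases still count as contamination in the truth.

Base reads are uniform random sequence with a synthetic quality profile:
per-position Gaussian scores around a mean that declines toward the 3'
end, clamped to [2, 41], emulating the well-known degradation of Illumina
quality along the read.

Trimming outcomes are classified per mate against the truth into five
categories — trimmed a clean read; trimmed exactly the adapter; trimmed
more; trimmed less; missed the adapter entirely — plus the clean-and-
untouched remainder, which map onto a TP/FP/FN/TN confusion matrix:
TP = trimmed exact, FP = trimmed clean + trimmed more, FN = trimmed less
+ missed, TN = clean untouched.  PPV, sensitivity, specificity and the
Matthews correlation coefficient are computed from that matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterator

import numpy as np

from .alignment import (
    AlignmentConfig,
    DEFAULT_ALIGNMENT,
    decode,
    encode,
    reverse_complement_codes,
)
from .fastq_io import Read
from .trimmer import (
    DEFAULT_ADAPTER1,
    DEFAULT_ADAPTER2,
    TrimConfig,
    trim_adapter_3prime_single,
    trim_adapter_pair,
)

TRIMMED_NO_ADAPTER = "trimmed_no_adapter"
TRIMMED_EXACT = "trimmed_exact"
TRIMMED_MORE = "trimmed_more"
TRIMMED_LESS = "trimmed_less"
MISSED_ADAPTER = "missed_adapter"
UNTOUCHED_NO_ADAPTER = "untouched_no_adapter"

CATEGORIES = (
    TRIMMED_NO_ADAPTER,
    TRIMMED_EXACT,
    TRIMMED_MORE,
    TRIMMED_LESS,
    MISSED_ADAPTER,
)


@dataclass(frozen=True)
class QualityModel:
    """Per-position Gaussian Phred model with 3'-declining mean.

    The mean runs from ``mean_start`` at the first cycle to ``mean_end``
    at the last along a mildly convex curve; scores have standard
    deviation ``sd`` and are clamped to ``[q_min, q_max]``.
    """

    mean_start: float = 38.0
    mean_end: float = 25.0
    sd: float = 5.0
    q_min: int = 2
    q_max: int = 41
    curve: float = 1.5

    def position_means(self, length: int) -> np.ndarray:
        x = np.linspace(0.0, 1.0, length)
        return self.mean_start - (self.mean_start - self.mean_end) * x**self.curve

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        q = rng.normal(self.position_means(length), self.sd)
        return np.clip(np.rint(q), self.q_min, self.q_max).astype(np.int16)


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 1_000_000
    read_length: int = 75
    insert_min: int = 0
    insert_max: int = 200
    adapter1: str = DEFAULT_ADAPTER1
    adapter2: str = DEFAULT_ADAPTER2
    seed: int = 1
    quality_model: QualityModel = field(default_factory=QualityModel)
    #: disable quality-driven substitution errors (idealised sequencing)
    error_free: bool = False

    def __post_init__(self) -> None:
        if self.insert_min > self.insert_max:
            raise ValueError("empty insert range")
        if not self.adapter1 or not self.adapter2 or self.adapter1 == self.adapter2:
            raise ValueError("adapters must be non-empty and distinct")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated pair."""

    insert_length: int
    adapter_length: int
    overlapping: bool
    contaminated: bool


@dataclass
class OutcomeCounts:
    trimmed_no_adapter: int = 0
    trimmed_exact: int = 0
    trimmed_more: int = 0
    trimmed_less: int = 0
    missed_adapter: int = 0
    untouched_no_adapter: int = 0

    def add(self, category: str) -> None:
        setattr(self, category, getattr(self, category) + 1)

    @property
    def total(self) -> int:
        return (
            self.trimmed_no_adapter
            + self.trimmed_exact
            + self.trimmed_more
            + self.trimmed_less
            + self.missed_adapter
            + self.untouched_no_adapter
        )

    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) under the category-to-confusion mapping."""
        tp = self.trimmed_exact
        fp = self.trimmed_no_adapter + self.trimmed_more
        fn = self.trimmed_less + self.missed_adapter
        tn = self.untouched_no_adapter
        return tp, fp, fn, tn


@dataclass(frozen=True)
class Metrics:
    """PPV / sensitivity / specificity / MCC; ``None`` marks an undefined
    (zero-denominator) value."""

    ppv: float | None
    sen: float | None
    spec: float | None
    mcc: float | None

    def rounded(self, digits: int = 2) -> "Metrics":
        rd = lambda v: None if v is None else round(v, digits)
        return Metrics(rd(self.ppv), rd(self.sen), rd(self.spec), rd(self.mcc))


def evaluate(counts: OutcomeCounts) -> Metrics:
    """Confusion-matrix metrics from classified trimming outcomes.

    ``PPV = TP/(TP+FP)``, ``SEN = TP/(TP+FN)``, ``SPEC = TN/(TN+FP)`` and
    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.
    Any zero denominator yields ``None`` for that metric.
    """
    tp, fp, fn, tn = counts.confusion()
    ppv = tp / (tp + fp) if tp + fp else None
    sen = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return Metrics(ppv, sen, spec, mcc)


def _random_codes(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def synth_base_pair(
    cfg: SimConfig, rng: np.random.Generator, pair_id: str = "sim"
) -> tuple[Read, Read]:
    """A raw read pair before any insert-length construction is applied.

    Both mates are independent uniform-random sequence with qualities
    drawn from the quality model — the stand-in for reads taken from a
    real sequencing run.
    """
    length = cfg.read_length
    r1 = Read(
        pair_id + "/1", decode(_random_codes(length, rng)),
        cfg.quality_model.sample(length, rng),
    )
    r2 = Read(
        pair_id + "/2", decode(_random_codes(length, rng)),
        cfg.quality_model.sample(length, rng),
    )
    return r1, r2


def mutate_by_quality(
    sequence: str, qualities: np.ndarray, rng: np.random.Generator
) -> str:
    """Substitute each base with probability ``Pe = 10^(-Q/10)``.

    Substitutions draw uniformly among the three other bases; N positions
    are left untouched.
    """
    codes = encode(sequence).copy()
    if len(sequence) != len(qualities):
        raise ValueError("sequence and qualities must have equal length")
    pe = 10.0 ** (-np.asarray(qualities, dtype=np.float64) / 10.0)
    hits = (rng.random(codes.size) < pe) & (codes < 4)
    n_hits = int(hits.sum())
    if n_hits:
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=n_hits)) % 4
    return decode(codes)


def build_truth_pair(
    cfg: SimConfig, rng: np.random.Generator, pair_id: str = "sim"
) -> tuple[Read, Read, TruthRecord]:
    """One simulated pair plus its ground truth, per the three-case rules."""
    lr = cfg.read_length
    r1, r2 = synth_base_pair(cfg, rng, pair_id)
    li = int(rng.integers(cfg.insert_min, cfg.insert_max + 1))
    truth = TruthRecord(
        insert_length=li,
        adapter_length=max(0, lr - li),
        overlapping=lr <= li < 2 * lr,
        contaminated=li < lr,
    )
    if li >= 2 * lr:
        return r1, r2, truth
    if li >= lr:
        # Overlap without contamination: rewrite read 2's 3' end with the
        # reverse complement of the shared insert subsequence from read 1,
        # then mutate only the newly written part.
        overlap = 2 * lr - li
        rc = decode(reverse_complement_codes(encode(r1.sequence[li - lr : lr])))
        head = r2.sequence[: lr - overlap]
        tail = rc if cfg.error_free else mutate_by_quality(
            rc, r2.qualities[lr - overlap :], rng
        )
        r2 = Read(r2.identifier, head + tail, r2.qualities)
        return r1, r2, truth
    # Contamination: insert from read 1, adapters appended, whole reads
    # mutated afterwards.
    insert = r1.sequence[:li]
    seq1 = _fill(insert + cfg.adapter1, lr, rng)
    rc_insert = decode(reverse_complement_codes(encode(insert)))
    seq2 = _fill(rc_insert + cfg.adapter2, lr, rng)
    if not cfg.error_free:
        seq1 = mutate_by_quality(seq1, r1.qualities, rng)
        seq2 = mutate_by_quality(seq2, r2.qualities, rng)
    r1 = Read(r1.identifier, seq1, r1.qualities)
    r2 = Read(r2.identifier, seq2, r2.qualities)
    return r1, r2, truth


def _fill(construct: str, length: int, rng: np.random.Generator) -> str:
    """Truncate to the read length, padding with off-template random bases."""
    if len(construct) >= length:
        return construct[:length]
    pad = decode(_random_codes(length - len(construct), rng))
    return construct + pad


def simulate_pairs(cfg: SimConfig) -> Iterator[tuple[Read, Read, TruthRecord]]:
    rng = np.random.default_rng(cfg.seed)
    for i in range(cfg.n_pairs):
        yield build_truth_pair(cfg, rng, pair_id=f"sim_{i}")


def classify_outcome(bases_removed: int, truth: TruthRecord) -> str:
    """Assign one mate's trimming result to its outcome category."""
    if truth.adapter_length == 0:
        return TRIMMED_NO_ADAPTER if bases_removed > 0 else UNTOUCHED_NO_ADAPTER
    if bases_removed == truth.adapter_length:
        return TRIMMED_EXACT
    if bases_removed > truth.adapter_length:
        return TRIMMED_MORE
    if bases_removed > 0:
        return TRIMMED_LESS
    return MISSED_ADAPTER


@dataclass
class BenchmarkResult:
    mate1: OutcomeCounts
    mate2: OutcomeCounts
    n_pairs: int

    @property
    def combined(self) -> OutcomeCounts:
        out = OutcomeCounts()
        for cat in CATEGORIES + (UNTOUCHED_NO_ADAPTER,):
            setattr(out, cat, getattr(self.mate1, cat) + getattr(self.mate2, cat))
        return out


def run_paired_benchmark(
    sim_cfg: SimConfig,
    trim_cfg: TrimConfig | None = None,
    align_cfg: AlignmentConfig = DEFAULT_ALIGNMENT,
) -> BenchmarkResult:
    """Simulate pairs, run paired adapter trimming only, classify per mate.

    Matching the published protocol, no N/quality trimming or filtering is
    applied: the benchmark isolates adapter identification.
    """
    trim_cfg = trim_cfg or TrimConfig(
        adapter1=sim_cfg.adapter1, adapter2=sim_cfg.adapter2
    )
    m1, m2 = OutcomeCounts(), OutcomeCounts()
    for r1, r2, truth in simulate_pairs(sim_cfg):
        _, _, a1, a2, _ = trim_adapter_pair(r1, r2, trim_cfg, align_cfg)
        m1.add(classify_outcome(a1.bases_removed_3p, truth))
        m2.add(classify_outcome(a2.bases_removed_3p, truth))
    return BenchmarkResult(mate1=m1, mate2=m2, n_pairs=sim_cfg.n_pairs)


def run_single_end_benchmark(
    sim_cfg: SimConfig,
    trim_cfg: TrimConfig | None = None,
    align_cfg: AlignmentConfig = DEFAULT_ALIGNMENT,
) -> OutcomeCounts:
    """Single-end benchmark over mate 1 of each simulated pair."""
    trim_cfg = trim_cfg or TrimConfig(
        adapter1=sim_cfg.adapter1, adapter2=sim_cfg.adapter2
    )
    counts = OutcomeCounts()
    for r1, _, truth in simulate_pairs(sim_cfg):
        _, action = trim_adapter_3prime_single(r1, trim_cfg, align_cfg)
        counts.add(classify_outcome(action.bases_removed_3p, truth))
    return counts


# ---------------------------------------------------------------------------
# File-based interface (simulate-to-files, evaluate-from-files)

TRUTH_HEADER = "pair_id\tread_length\tinsert_length\tadapter_length\toverlapping\tcontaminated"


def write_truth(records: list[tuple[str, int, TruthRecord]], sink: IO) -> None:
    sink.write(TRUTH_HEADER + "\n")
    for pair_id, read_length, truth in records:
        sink.write(
            f"{pair_id}\t{read_length}\t{truth.insert_length}\t"
            f"{truth.adapter_length}\t{int(truth.overlapping)}\t"
            f"{int(truth.contaminated)}\n"
        )


def read_truth(source: IO) -> dict[str, tuple[int, TruthRecord]]:
    header = source.readline()
    if header.strip() != TRUTH_HEADER.strip():
        raise ValueError("unrecognised truth file header")
    out: dict[str, tuple[int, TruthRecord]] = {}
    for line in source:
        pair_id, lr, li, la, ov, ct = line.rstrip("\n").split("\t")
        out[pair_id] = (
            int(lr),
            TruthRecord(int(li), int(la), bool(int(ov)), bool(int(ct))),
        )
    return out


def evaluate_trimmed_reads(
    trimmed_lengths: dict[str, int],
    truth: dict[str, tuple[int, TruthRecord]],
) -> OutcomeCounts:
    """Classify trimmed output (by pair id) against a truth table.

    A read absent from the trimmed output is treated as trimmed to length
    zero (e.g. discarded after complete adapter removal).
    """
    counts = OutcomeCounts()
    for pair_id, (read_length, record) in truth.items():
        out_len = trimmed_lengths.get(pair_id, 0)
        counts.add(classify_outcome(read_length - out_len, record))
    return counts
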