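"""Read quality control and ICDS tag detection.

The cleanup applied to raw reads before alignment: adapter clipping,
removal of non-A/C/G/T bases from the 5' end, 3' trimming of bases below
Q20, then removal of reads with >10% N calls or shorter than 25 bp.  In
ICDS mode the ligated duplex-tag sequence is additionally detected at the
read 5' end (it marks iodine-cleaved, i.e. PT-derived, ends) and trimmed;
only tagged reads survive, modelling the PCR enrichment of tagged
fragments.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

# R1 strand of the duplex tag ligated onto iodine-cleaved ends; sequenced
# reads from tagged fragments begin with this sequence.
TAG_SEQUENCE = "GCTGGAATTCGCGGTTAAAT"

# TruSeq adapter stub used as the default 3' adapter.
ILLUMINA_ADAPTER = "AGATCGGAAGAGC"

_LEADING_NON_ACGT = re.compile(r"^[^ACGT]+")

#: removal reasons, in reporting order
REMOVAL_REASONS = ("adapter", "five_prime_n", "quality",
                   "untagged", "n_fraction", "length")


@dataclass(frozen=True)
class SequencedRead:
    """A read with Phred+33 quality string; ``tagged`` is set by tag detection."""

    id: str
    bases: str
    quals: str
    tagged: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: bases/quals length mismatch "
                f"({len(self.bases)} vs {len(self.quals)})")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.quals]


@dataclass
class QCParams:
    """Tunable QC thresholds; defaults follow the published pipeline rules."""

    min_length: int = 25
    max_n_fraction: float = 0.10
    quality_floor: int = 20
    adapters: tuple[str, ...] = (ILLUMINA_ADAPTER,)
    tag: str = TAG_SEQUENCE
    tag_mismatches: int = 1
    mode: str = "PTIC"  # "ICDS" or "PTIC"
    min_adapter_overlap: int = 8
    trim_tail_base: bool = False  # remove one A/T after the tag (ligation artifact)

    def __post_init__(self) -> None:
        if not 0 <= self.max_n_fraction <= 1:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.mode not in ("ICDS", "PTIC"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class QCReport:
    """Per-rule accounting; removals partition the input exactly."""

    input_reads: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in REMOVAL_REASONS})
    adapter_clipped: int = 0
    tagged_reads: int = 0
    surviving_reads: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "input_reads": self.input_reads,
                "removed": self.removed,
                "adapter_clipped": self.adapter_clipped,
                "tagged_reads": self.tagged_reads,
                "surviving_reads": self.surviving_reads,
            }, fh, indent=2)

    def check_conservation(self) -> bool:
        return self.surviving_reads + sum(self.removed.values()) == self.input_reads


def _hamming(a: str, b: str, limit: int | None = None) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def clip_adapters(read: SequencedRead, adapters: Sequence[str],
                  min_overlap: int = 8) -> tuple[SequencedRead, bool]:
    """Remove the longest 3'-terminal read segment matching an adapter prefix.

    Overlaps of at least ``min_overlap`` bases are considered, allowing one
    mismatch per 10 bases of overlap.  Returns the (possibly shortened)
    read and whether anything was clipped.
    """
    best = 0
    for adapter in adapters:
        top = min(len(read.bases), len(adapter))
        for ov in range(top, min_overlap - 1, -1):
            if ov <= best:
                break
            allowed = ov // 10
            if _hamming(read.bases[-ov:], adapter[:ov], allowed) <= allowed:
                best = ov
                break
    if best == 0:
        return read, False
    cut = len(read.bases) - best
    return replace(read, bases=read.bases[:cut], quals=read.quals[:cut]), True


def trim_5prime_non_acgt(read: SequencedRead) -> SequencedRead:
    """Remove the leading maximal run of non-A/C/G/T symbols."""
    m = _LEADING_NON_ACGT.match(read.bases)
    if not m:
        return read
    k = m.end()
    return replace(read, bases=read.bases[k:], quals=read.quals[k:])


def trim_low_quality(read: SequencedRead, quality_floor: int = 20) -> SequencedRead:
    """Trim 3'-terminal bases while the terminal base quality is < floor."""
    cutoff = chr(quality_floor + 33)
    j = len(read.quals)
    while j > 0 and read.quals[j - 1] < cutoff:
        j -= 1
    if j == len(read.quals):
        return read
    return replace(read, bases=read.bases[:j], quals=read.quals[:j])


def filter_read(read: SequencedRead, params: QCParams) -> tuple[bool, str | None]:
    """Keep/discard decision after trimming: N-fraction rule, then length.

    "More than 10% N" and "less than 25 bp" are read strictly.
    """
    n = len(read.bases)
    n_frac = read.bases.count("N") / n if n else 0.0
    if n_frac > params.max_n_fraction:
        return False, "n_fraction"
    if n < params.min_length:
        return False, "length"
    return True, None


def detect_and_trim_tag(read: SequencedRead, tag: str = TAG_SEQUENCE,
                        tag_mismatches: int = 1,
                        trim_tail_base: bool = False) -> SequencedRead:
    """Detect the duplex tag at the 5' end and trim it.

    A match allows up to ``tag_mismatches`` substitutions (no indels).  With
    ``trim_tail_base`` one A/T immediately after the tag (an A-tailing
    ligation artifact) is also removed; off by default because true
    cleavage-derived inserts begin with AAC/TTC and a lone artifact base is
    indistinguishable from them.
    """
    if not tag:
        raise ValueError("tag must be non-empty")
    k = len(tag)
    if len(read.bases) < k:
        return replace(read, tagged=False)
    if _hamming(read.bases[:k], tag, tag_mismatches) > tag_mismatches:
        return replace(read, tagged=False)
    if trim_tail_base and len(read.bases) > k and read.bases[k] in "AT":
        k += 1
    return replace(read, bases=read.bases[k:], quals=read.quals[k:], tagged=True)


def run_qc(reads: Iterable[SequencedRead],
           params: QCParams) -> tuple[list[SequencedRead], QCReport]:
    """Full QC pipeline: clip adapters, trim 5' non-ACGT, (ICDS: tag), trim
    low-quality 3' bases, then apply the N-fraction and length filters.

    A read emptied by a trimming step is removed under that step's reason;
    in ICDS mode untagged reads are removed before the content filters.
    """
    report = QCReport()
    survivors: list[SequencedRead] = []
    icds = params.mode == "ICDS"
    for read in reads:
        report.input_reads += 1
        if params.adapters:
            read, clipped = clip_adapters(read, params.adapters,
                                          params.min_adapter_overlap)
            if clipped:
                report.adapter_clipped += 1
            if not read.bases:
                report.removed["adapter"] += 1
                continue
        read = trim_5prime_non_acgt(read)
        if not read.bases:
            report.removed["five_prime_n"] += 1
            continue
        if icds:
            read = detect_and_trim_tag(read, params.tag, params.tag_mismatches,
                                       params.trim_tail_base)
            if read.tagged:
                report.tagged_reads += 1
        read = trim_low_quality(read, params.quality_floor)
        if not read.bases:
            report.removed["quality"] += 1
            continue
        if icds and not read.tagged:
            report.removed["untagged"] += 1
            continue
        keep, reason = filter_read(read, params)
        if not keep:
            report.removed[reason] += 1
            continue
        survivors.append(read)
        report.surviving_reads += 1
    return survivors, report


# -- FASTQ I/O ---------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[SequencedRead]:
    """Read FASTQ records (Phred+33, gzip-transparent)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(path) as fh:
        return [SequencedRead(title.split()[0], bases, quals)
                for title, bases, quals in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[SequencedRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quals}\n")
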