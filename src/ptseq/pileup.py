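"""Alignment consumption, 5'-end pileups and spanning-read counts.

The two observables of iodine-cleavage sequencing at a motif locus are

* reads whose 5' end sits exactly at one of the site's cleavage points
  (evidence of an iodine-cleaved, hence PT-modified, molecule), and
* reads that fully contain the intact 4-mer with their 5' end elsewhere
  ("crossed"/spanning reads, evidence of an uncleaved molecule).

Alignments are consumed from SAM/BAM produced by any external aligner, or
from the built-in exact-match fixture mapper :func:`naive_align` so that
the test suite needs no aligner binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .genome import ControlSite, MotifSite, ReferenceSequence, reverse_complement


@dataclass(frozen=True)
class Alignment:
    """A mapped read: 0-based half-open reference interval plus strand."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int = 60
    tagged: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: empty alignment interval")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


def five_prime_end(a: Alignment) -> tuple[int, str]:
    """Reference coordinate of the read's first sequenced base."""
    return (a.start, "+") if a.strand == "+" else (a.end - 1, "-")


class EndPileup:
    """Per-contig, per-strand counts of aligned-read 5' ends plus an index
    of alignment intervals for spanning queries."""

    def __init__(self, contig_lengths: dict[str, int], mapq_floor: int = 0,
                 tagged_only: bool = False):
        self.contig_lengths = dict(contig_lengths)
        self.mapq_floor = mapq_floor
        self.tagged_only = tagged_only
        self.n_alignments = 0
        self._plus = {c: np.zeros(L, dtype=np.int64)
                      for c, L in self.contig_lengths.items()}
        self._minus = {c: np.zeros(L, dtype=np.int64)
                       for c, L in self.contig_lengths.items()}
        # interval index: per contig, parallel arrays over retained alignments
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._fives: dict[str, np.ndarray] = {}

    @classmethod
    def build(cls, alignments: Iterable[Alignment],
              contig_lengths: dict[str, int], mapq_floor: int = 0,
              tagged_only: bool = False) -> "EndPileup":
        self = cls(contig_lengths, mapq_floor, tagged_only)
        buf: dict[str, list[tuple[int, int, int]]] = {
            c: [] for c in self.contig_lengths}
        for a in alignments:
            if a.mapq < mapq_floor:
                continue
            if tagged_only and not a.tagged:
                continue
            if a.contig not in buf:
                raise KeyError(f"alignment contig {a.contig!r} not in reference")
            pos, strand = five_prime_end(a)
            if strand == "+":
                self._plus[a.contig][pos] += 1
            else:
                self._minus[a.contig][pos] += 1
            buf[a.contig].append((a.start, a.end, pos))
            self.n_alignments += 1
        for c, rows in buf.items():
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            self._starts[c] = arr[:, 0]
            self._ends[c] = arr[:, 1]
            self._fives[c] = arr[:, 2]
        return self

    def _contig(self, contig: str | None) -> str:
        if contig is not None:
            return contig
        if len(self.contig_lengths) == 1:
            return next(iter(self.contig_lengths))
        raise ValueError("contig must be given for a multi-contig pileup")

    def count_ends_at(self, position: int, strand: str,
                      contig: str | None = None) -> int:
        c = self._contig(contig)
        track = self._plus if strand == "+" else self._minus
        if not 0 <= position < self.contig_lengths[c]:
            return 0
        return int(track[c][position])

    def count_spanning(self, site: MotifSite | ControlSite) -> int:
        """Alignments fully containing the site's 4-mer whose 5' end is not
        one of the site's (pseudo-)cleavage points."""
        c = site.contig
        if c not in self._starts or self._starts[c].size == 0:
            return 0
        a, b = site.start, site.start + 4
        mask = (self._starts[c] <= a) & (self._ends[c] >= b)
        mask &= (self._fives[c] != site.plus_cleavage)
        mask &= (self._fives[c] != site.minus_cleavage)
        return int(mask.sum())

    def strand_track(self, contig: str, strand: str) -> np.ndarray:
        return (self._plus if strand == "+" else self._minus)[contig]

    def total_end_count(self) -> int:
        return int(sum(t.sum() for t in self._plus.values())
                   + sum(t.sum() for t in self._minus.values()))


def build_end_pileup(alignments: Iterable[Alignment],
                     contig_lengths: dict[str, int], mapq_floor: int = 0,
                     tagged_only: bool = False) -> EndPileup:
    return EndPileup.build(alignments, contig_lengths, mapq_floor, tagged_only)


def count_ends_at(pileup: EndPileup, position: int, strand: str,
                  contig: str | None = None) -> int:
    return pileup.count_ends_at(position, strand, contig)


def count_spanning(pileup: EndPileup, site: MotifSite | ControlSite) -> int:
    return pileup.count_spanning(site)


# -- SAM I/O -----------------------------------------------------------------

def parse_sam(path) -> list[Alignment]:
    """Primary mapped alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are excluded; strand
    comes from the reverse flag and the end from CIGAR reference
    consumption.  A ``ptseq`` tagged read is marked with an ``XT:i:1``
    auxiliary tag by the simulator/writer and the flag is carried through.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header with @SQ lines is required")
        out = []
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_sequence is not None and rec.cigartuples:
                if rec.infer_query_length() != len(rec.query_sequence):
                    raise ValueError(
                        f"{path}: CIGAR/sequence length mismatch for "
                        f"{rec.query_name!r}")
            tagged = bool(rec.get_tag("XT")) if rec.has_tag("XT") else False
            out.append(Alignment(
                read_id=rec.query_name,
                contig=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                tagged=tagged,
            ))
    return out


def write_sam(alignments: Sequence[Alignment],
              contig_lengths: dict[str, int], path) -> None:
    """Write alignments as coordinate-unsorted SAM (matched M-only CIGAR,
    no sequence).  Tagged alignments carry ``XT:i:1``."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": L} for c, L in contig_lengths.items()]}
    tid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = a.read_id
            rec.flag = 16 if a.strand == "-" else 0
            rec.reference_id = tid[a.contig]
            rec.reference_start = a.start
            rec.mapping_quality = a.mapq
            rec.cigartuples = [(0, a.end - a.start)]
            if a.tagged:
                rec.set_tag("XT", 1)
            fh.write(rec)


# -- fixture mapper ----------------------------------------------------------

def naive_align(reads, ref: ReferenceSequence, seed_length: int = 20,
                ) -> tuple[list[Alignment], dict[str, int]]:
    """Exact-match fixture mapper (k-mer seed and verify).

    Places each read, or its reverse complement, by full-length exact match
    against the reference; reads with zero or multiple placements are
    dropped and tallied.  Deterministic.  This exists so the pipeline can be
    exercised end-to-end without an external aligner; it is not a
    production aligner (reads carrying a sequencing error do not align and
    are dropped, uniformly at random with respect to position).
    """
    genome = ref.seq
    index: dict[str, list[int]] = {}
    for i in range(len(genome) - seed_length + 1):
        index.setdefault(genome[i:i + seed_length], []).append(i)
    alignments: list[Alignment] = []
    dropped = {"too_short": 0, "unaligned": 0, "ambiguous": 0}
    for read in reads:
        n = len(read.bases)
        if n < seed_length:
            dropped["too_short"] += 1
            continue
        hits: list[tuple[int, str]] = []
        for seq, strand in ((read.bases, "+"),
                            (reverse_complement(read.bases), "-")):
            for p in index.get(seq[:seed_length], ()):
                if genome[p:p + n] == seq:
                    hits.append((p, strand))
        if not hits:
            dropped["unaligned"] += 1
        elif len(hits) > 1:
            dropped["ambiguous"] += 1
        else:
            p, strand = hits[0]
            alignments.append(Alignment(read.id, ref.name, p, p + n, strand,
                                        mapq=60,
                                        tagged=getattr(read, "tagged", False)))
    return alignments, dropped
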