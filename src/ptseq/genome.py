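"""Reference sequences and GAAC/GTTC motif geometry.

Bacterial phosphorothioate (PT) modification is laid down by the Dnd system
on both strands of a short consensus, in enterobacteria the 4-mer GAAC/GTTC:
a forward-strand ``GpsAAC`` is paired with ``GpsTTC`` on the reverse strand
of the same locus.  Iodine cleaves each modified strand immediately 3' of
the PT-bearing G, so cleavage-derived reads begin with ``AAC...`` (plus
strand) or ``TTC...`` (minus strand).  This module locates every motif
occurrence on a reference, attaches the two strand-specific cleavage
coordinates, and samples random non-motif control positions used for
background (shear) frequency estimation.

Coordinates are 0-based, half-open throughout; BED output follows the same
convention.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

DEFAULT_MOTIFS: tuple[str, ...] = ("GAAC", "GTTC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGT = re.compile(r"[^ACGT]")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference contig.

    Residues are upper-case; IUPAC ambiguity codes are masked to ``N`` on
    load (PT calling on ambiguous reference bases is meaningless, and ``N``
    can never match a motif).  ``circular`` enables origin-wrapping motif
    windows for circular bacterial chromosomes/plasmids.
    """

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"reference {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifSite:
    """A bistranded GAAC/GTTC locus with its two cleavage points.

    ``start`` is the forward-strand coordinate of the first motif base.
    For a forward GAAC the reverse strand reads GTTC with its G at forward
    coordinate ``start+3``; iodine cleavage 3' of each G puts the 5'-most
    base of the downstream fragment at ``start+1`` on the plus strand and
    ``start+2`` on the minus strand (identical arithmetic for a forward
    GTTC, whose reverse strand is GAAC).
    """

    contig: str
    start: int
    forward_motif: str
    plus_cleavage: int
    minus_cleavage: int

    @classmethod
    def at(cls, contig: str, start: int, motif: str, length: int,
           circular: bool = False) -> "MotifSite":
        pc, mc = start + 1, start + 2
        if circular:
            pc, mc = pc % length, mc % length
        return cls(contig, start, motif, pc, mc)

    @property
    def end(self) -> int:
        return self.start + 4


@dataclass(frozen=True)
class ControlSite:
    """A random non-motif position used to estimate the shear background.

    The two pseudo-cleavage points mirror the motif geometry (position+1 on
    the plus strand, position+2 on the minus strand) so control frequencies
    are computed with exactly the same machinery as real sites.
    """

    contig: str
    position: int

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        return self.position + 4

    @property
    def plus_cleavage(self) -> int:
        return self.position + 1

    @property
    def minus_cleavage(self) -> int:
        return self.position + 2


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, circular: bool = False) -> list[ReferenceSequence]:
    """Read a (possibly gzipped) multi-record FASTA.

    Residues are upper-cased and any non-A/C/G/T symbol is masked to ``N``.
    Raises on an empty file and on sequence data appearing before the first
    header (with the offending line number).
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    seen_header = False
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise ValueError(
                f"{path}: malformed FASTA, sequence before header at line {i}")
    if not seen_header:
        raise ValueError(f"{path}: empty or headerless FASTA")
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    out = []
    for rec in records:
        seq = _NON_ACGT.sub("N", str(rec.seq).upper())
        out.append(ReferenceSequence(rec.id, seq, circular=circular))
    return out


def write_fasta(refs: Iterable[ReferenceSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.seq), width):
                fh.write(ref.seq[i:i + width] + "\n")


def scan_motifs(ref: ReferenceSequence,
                motifs: Sequence[str] = DEFAULT_MOTIFS) -> list[MotifSite]:
    """All forward-strand motif occurrences, sorted by start.

    Because the motif set is reverse-complement closed (GAAC <-> GTTC), the
    forward scan enumerates every bistranded locus exactly once.  On a
    circular reference, windows wrapping the origin are included with
    cleavage coordinates taken modulo the length.
    """
    for m in motifs:
        if len(m) != 4 or _NON_ACGT.search(m):
            raise ValueError(f"motif {m!r} is not a 4-mer over A/C/G/T")
    L = len(ref.seq)
    starts: list[tuple[int, str]] = []
    for m in motifs:
        pos = ref.seq.find(m)
        while pos != -1:
            starts.append((pos, m))
            pos = ref.seq.find(m, pos + 1)
    if ref.circular and L >= 4:
        junction = ref.seq[L - 3:] + ref.seq[:3]
        for m in motifs:
            for i in range(3):
                if junction[i:i + 4] == m:
                    starts.append((L - 3 + i, m))
    starts.sort()
    return [MotifSite.at(ref.name, s, m, L, ref.circular) for s, m in starts]


def sample_control_sites(ref: ReferenceSequence,
                         sites: Sequence[MotifSite],
                         n: int = 10,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> list[ControlSite]:
    """Draw ``n`` distinct non-motif control positions, uniformly at random.

    A position ``p`` is eligible when no motif 4-mer overlaps
    ``[p-3, p+4)``, i.e. neither pseudo-cleavage point can fall inside a
    real motif.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(ref.seq)
    if L < 4:
        raise ValueError(f"reference too short ({L} bp) for control sites")
    eligible = np.ones(L - 3, dtype=bool)  # candidate 4-mer starts
    for site in sites:
        lo = max(0, site.start - 3)
        hi = min(L - 3, site.start + 7)  # exclusive
        eligible[lo:hi] = False
        if ref.circular and site.start + 7 > L - 3:
            eligible[: (site.start + 7) - (L - 3)] = False
    idx = np.flatnonzero(eligible)
    if idx.size < n:
        raise ValueError(
            f"only {idx.size} eligible control positions, need {n}")
    chosen = np.sort(rng.choice(idx, size=n, replace=False))
    return [ControlSite(ref.name, int(p)) for p in chosen]


def write_sites_bed(sites: Iterable[MotifSite], path) -> None:
    """6-column BED of motif sites (forward-strand coordinates)."""
    with open(path, "w") as fh:
        fh.write("# ptseq motif sites: chrom start end motif score strand\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.start + 4}\t"
                     f"{s.forward_motif}\t0\t+\n")


def write_sites_tsv(sites: Iterable[MotifSite], path) -> None:
    """TSV of motif sites including both strand-specific cleavage points."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tforward_motif\t"
                 "plus_cleavage\tminus_cleavage\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.start + 4}\t"
                     f"{s.forward_motif}\t{s.plus_cleavage}\t"
                     f"{s.minus_cleavage}\n")
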