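"""Standard-format writers and the circular genome map.

Outputs are chosen to load directly in a genome browser: BED for called or
passing sites, one bedGraph per strand for 5'-end counts, a TSV with the
full per-site table, and a JSON run summary.  The circular map mirrors the
published presentation: concentric rings (by tagged-read count for ICDS,
by modification frequency for PT-IC-Seq) with GAAC sites drawn blue and
GTTC sites red at angle 2*pi*start/genome_length.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .callers import IcdsCall, RingAssignment, SiteQuant, bin_sites_for_map
from .pileup import EndPileup


def quants_to_frame(quants: Sequence[SiteQuant]) -> pd.DataFrame:
    return pd.DataFrame({
        "contig": [q.site.contig for q in quants],
        "start": [q.site.start for q in quants],
        "end": [q.site.end for q in quants],
        "motif": [q.site.forward_motif for q in quants],
        "n_end_plus": [q.n_end_plus for q in quants],
        "n_end_minus": [q.n_end_minus for q in quants],
        "n_span": [q.n_span for q in quants],
        "frequency": [q.frequency for q in quants],
        "threshold": [q.threshold for q in quants],
        "passes": [q.passes_threshold for q in quants],
    })


def calls_to_frame(calls: Sequence[IcdsCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "contig": [c.site.contig for c in calls],
        "start": [c.site.start for c in calls],
        "end": [c.site.end for c in calls],
        "motif": [c.site.forward_motif for c in calls],
        "tagged_end_reads": [c.tagged_end_reads for c in calls],
        "modified": [c.modified for c in calls],
    })


def write_site_tracks(items: Sequence[SiteQuant] | Sequence[IcdsCall],
                      out_prefix, mode: str,
                      pileup: EndPileup | None = None) -> dict[str, Path]:
    """Write TSV + BED (+ per-strand bedGraphs when a pileup is given).

    The BED holds passing (PTIC) or modified (ICDS) sites; scores carry
    the raw tagged-end count (ICDS) or frequency x1000 (PTIC), since BED
    scores are integer-bounded.  Returns the paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if mode == "PTIC":
        frame = quants_to_frame(items)
        hits = [q for q in items if q.passes_threshold]
        bed_rows = [(q.site.contig, q.site.start, q.site.end,
                     q.site.forward_motif, int(round(1000 * q.frequency)), "+")
                    for q in hits]
    elif mode == "ICDS":
        frame = calls_to_frame(items)
        hits = [c for c in items if c.modified]
        bed_rows = [(c.site.contig, c.site.start, c.site.end,
                     c.site.forward_motif, c.tagged_end_reads, "+")
                    for c in hits]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    tsv = out_prefix.with_suffix(".tsv")
    frame.to_csv(tsv, sep="\t", index=False, na_rep="NA")
    paths["tsv"] = tsv

    bed = out_prefix.with_suffix(".bed")
    with open(bed, "w") as fh:
        fh.write(f"# ptseq {mode} sites\n")
        for row in bed_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    paths["bed"] = bed

    if pileup is not None:
        for strand, label in (("+", "plus"), ("-", "minus")):
            bg = out_prefix.parent / f"{out_prefix.name}.ends_{label}.bedGraph"
            with open(bg, "w") as fh:
                fh.write(f"track type=bedGraph name=ptseq_ends_{label}\n")
                for contig in pileup.contig_lengths:
                    track = pileup.strand_track(contig, strand)
                    for pos in np.flatnonzero(track):
                        fh.write(f"{contig}\t{pos}\t{pos + 1}\t"
                                 f"{int(track[pos])}\n")
            paths[f"bedgraph_{label}"] = bg

    rings = bin_sites_for_map(items, mode)
    per_ring = {r: 0 for r in (1, 2, 3, 4)}
    flagged = 0
    for asn in rings:
        if asn.in_range:
            per_ring[asn.ring] += 1
        else:
            flagged += 1
    summary = out_prefix.parent / f"{out_prefix.name}.summary.json"
    payload = {
        "mode": mode,
        "n_sites": len(items),
        "n_reported": len(hits),
        "ring_counts": per_ring,
        "out_of_range": flagged,
        "ptseq_version": __version__,
    }
    if mode == "PTIC" and items:
        payload["threshold"] = items[0].threshold
    with open(summary, "w") as fh:
        json.dump(payload, fh, indent=2)
    paths["summary"] = summary
    return paths


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return rows


def plot_circular_map(assignments: Sequence[RingAssignment],
                      genome_length: int, mode: str, path) -> dict[int, int]:
    """Concentric-ring map of called sites on a circular genome layout.

    Rings 1..4 (ICDS) or 1..3 (PTIC) from inner to outer; GAAC sites blue,
    GTTC red, at angle 2*pi*start/genome_length.  Returns the per-ring dot
    tally actually drawn.
    """
    n_rings = 4 if mode == "ICDS" else 3
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_ylim(0, n_rings + 1.5)
    ax.set_xticks([])
    ax.set_yticks([])
    theta_grid = np.linspace(0, 2 * np.pi, 256)
    for r in range(1, n_rings + 1):
        ax.plot(theta_grid, np.full_like(theta_grid, r), lw=0.6,
                color="0.75", zorder=1)
    tally = {r: 0 for r in range(1, n_rings + 1)}
    for asn in assignments:
        if not asn.in_range:
            continue
        site = asn.item.site
        theta = 2 * np.pi * site.start / genome_length
        color = "tab:blue" if site.forward_motif == "GAAC" else "tab:red"
        ax.scatter([theta], [asn.ring], s=8, color=color, zorder=2)
        tally[asn.ring] += 1
    ax.set_title(f"PT sites ({mode}); rings 1-{n_rings} inner to outer")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return tally


def write_manifest(path, config: dict) -> None:
    """Run manifest: configuration, seeds and version, for reproducibility."""
    payload = {"ptseq_version": __version__, "config": config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
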