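"""ICDS site calling and PT-IC-Seq per-site frequency quantification.

ICDS (qualitative): a motif site is called PT-modified when strictly more
than ``min_reads`` (default 50) tagged reads end at its cleavage points.

PT-IC-Seq (quantitative): the per-site modification frequency is

    frequency = n_end / (n_end + n_span)

where ``n_end`` counts reads ending exactly at the site's two cleavage
points (plus strand at start+1, minus strand at start+2) and ``n_span``
counts reads containing the intact 4-mer internally.  Random sonication
shear also deposits read ends at cleavage points, so the background is
estimated at randomly drawn non-motif control sites and sites must exceed
a control-derived threshold to be reported.

The decision threshold defaults to the control mean plus six binomial
standard errors of a control-site frequency estimate at the observed
control coverage.
``k_sd=0`` reproduces the plain control-average rule; the default guards
the genome-wide scan against the ~half of unmodified sites that exceed the
control *mean* by symmetry.  See docs/methods.md for the derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import ControlSite, MotifSite
from .pileup import EndPileup

DEFAULT_MIN_READS = 50
DEFAULT_K_SD = 6.0

# Ring bins of the circular genome maps: ICDS by tagged-end read count,
# PT-IC-Seq by modification frequency.
ICDS_RING_EDGES = (50, 1050, 2050, 3050)           # (50,1050] (1050,2050] (2050,3050] (3050,inf)
PTIC_RING_EDGES = (0.05, 0.15, 0.25, 0.35)          # [5,15) [15,25) [25,35] percent


@dataclass(frozen=True)
class IcdsCall:
    site: MotifSite
    tagged_end_reads: int
    modified: bool


@dataclass(frozen=True)
class SiteQuant:
    site: MotifSite
    n_end_plus: int
    n_end_minus: int
    n_span: int
    frequency: float | None
    threshold: float
    passes_threshold: bool

    @property
    def n_end(self) -> int:
        return self.n_end_plus + self.n_end_minus


@dataclass(frozen=True)
class ControlStats:
    control_sites: tuple[ControlSite, ...]
    frequencies: tuple[float | None, ...]
    mean_frequency: float
    sd_frequency: float
    k_sd: float
    threshold: float

    @property
    def n_defined(self) -> int:
        return sum(f is not None for f in self.frequencies)


def site_frequency(n_end: int, n_span: int) -> float | None:
    """n_end / (n_end + n_span); ``None`` when the site has no coverage."""
    if n_end < 0 or n_span < 0:
        raise ValueError("counts must be non-negative")
    total = n_end + n_span
    if total == 0:
        return None
    return n_end / total


def site_end_counts(pileup: EndPileup,
                    site: MotifSite | ControlSite) -> tuple[int, int]:
    """(plus-strand, minus-strand) read-end counts at the site's cleavage
    points."""
    n_plus = pileup.count_ends_at(site.plus_cleavage, "+", site.contig)
    n_minus = pileup.count_ends_at(site.minus_cleavage, "-", site.contig)
    return n_plus, n_minus


def call_icds(pileup: EndPileup, sites: Sequence[MotifSite],
              min_reads: int = DEFAULT_MIN_READS) -> list[IcdsCall]:
    """One call per site; modified iff tagged-end reads strictly exceed
    ``min_reads``.  Requires a pileup built from tagged reads only."""
    if not pileup.tagged_only:
        raise ValueError(
            "ICDS calling requires a pileup built in tag mode "
            "(EndPileup.build(..., tagged_only=True))")
    calls = []
    for site in sites:
        n_plus, n_minus = site_end_counts(pileup, site)
        n = n_plus + n_minus
        calls.append(IcdsCall(site, n, n > min_reads))
    return calls


def control_threshold(pileup: EndPileup, controls: Sequence[ControlSite],
                      k_sd: float = DEFAULT_K_SD) -> ControlStats:
    """Background statistics at the control sites.

    Each control frequency is computed with the same end/spanning machinery
    as a real site, using its pseudo-cleavage points.  The threshold is
    mean + k_sd * se, where se = sqrt(mean*(1-mean)/n_mean) is the binomial
    standard error implied by the mean control coverage.  The model-based
    se is used rather than the empirical sd because a handful of controls
    (default 10) cannot estimate their own spread reliably; the empirical
    sd is still reported.  ``k_sd=0`` gives the plain control mean.
    """
    freqs: list[float | None] = []
    totals: list[int] = []
    for ctl in controls:
        n_plus, n_minus = site_end_counts(pileup, ctl)
        n_span = pileup.count_spanning(ctl)
        f = site_frequency(n_plus + n_minus, n_span)
        freqs.append(f)
        if f is not None:
            totals.append(n_plus + n_minus + n_span)
    defined = [f for f in freqs if f is not None]
    if not defined:
        raise ValueError(
            "no control site has any coverage; deeper sequencing is needed "
            "to estimate the shear background")
    mean = float(np.mean(defined))
    sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
    n_mean = float(np.mean(totals))
    se_model = math.sqrt(mean * (1.0 - mean) / n_mean) if n_mean > 0 else 0.0
    threshold = mean + k_sd * se_model
    return ControlStats(tuple(controls), tuple(freqs), mean, sd, k_sd, threshold)


def quantify_genome(pileup: EndPileup, sites: Sequence[MotifSite],
                    controls: Sequence[ControlSite] | None = None,
                    stats: ControlStats | None = None,
                    k_sd: float = DEFAULT_K_SD) -> list[SiteQuant]:
    """Per-site frequencies genome-wide; a site passes iff its frequency is
    defined and strictly greater than the control threshold."""
    if stats is None:
        if controls is None:
            raise ValueError("either controls or precomputed stats required")
        stats = control_threshold(pileup, controls, k_sd)
    quants = []
    for site in sites:
        n_plus, n_minus = site_end_counts(pileup, site)
        n_span = pileup.count_spanning(site)
        f = site_frequency(n_plus + n_minus, n_span)
        passes = f is not None and f > stats.threshold
        quants.append(SiteQuant(site, n_plus, n_minus, n_span, f,
                                stats.threshold, passes))
    quants.sort(key=lambda q: (q.site.contig, q.site.start))
    return quants


@dataclass(frozen=True)
class RingAssignment:
    """Ring index for the circular genome map; ``ring`` is None (and
    ``in_range`` False) for values outside the published bin ranges."""

    item: IcdsCall | SiteQuant
    ring: int | None
    in_range: bool


def bin_sites_for_map(calls: Sequence[IcdsCall] | Sequence[SiteQuant],
                      mode: str) -> list[RingAssignment]:
    """Assign map rings: ICDS by tagged-end count into (50,1050],
    (1050,2050], (2050,3050], (3050,inf); PT-IC-Seq by frequency into
    [5%,15%), [15%,25%), [25%,35%].  Out-of-range values are flagged, not
    dropped."""
    out = []
    if mode == "ICDS":
        e = ICDS_RING_EDGES
        for call in calls:
            n = call.tagged_end_reads
            if n <= e[0]:
                out.append(RingAssignment(call, None, False))
            elif n <= e[1]:
                out.append(RingAssignment(call, 1, True))
            elif n <= e[2]:
                out.append(RingAssignment(call, 2, True))
            elif n <= e[3]:
                out.append(RingAssignment(call, 3, True))
            else:
                out.append(RingAssignment(call, 4, True))
    elif mode == "PTIC":
        e = PTIC_RING_EDGES
        for quant in calls:
            f = quant.frequency
            if f is None or f < e[0] or f > e[3]:
                out.append(RingAssignment(quant, None, False))
            elif f < e[1]:
                out.append(RingAssignment(quant, 1, True))
            elif f < e[2]:
                out.append(RingAssignment(quant, 2, True))
            else:
                out.append(RingAssignment(quant, 3, True))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
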