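"""Locate GAAC/GTTC loci and their strand-specific cleavage points.

Every forward-strand GAAC is a reverse-strand GTTC at the same locus (and
vice versa), so one forward scan enumerates each bistranded PT candidate
site once.  Iodine cleaves each PT strand just 3' of the G: the plus-strand
cleavage point is start+1 (reads begin AAC...), the minus-strand point is
start+2 (reads begin TTC...).
"""

from ptseq import ReferenceSequence, sample_control_sites, scan_motifs

ref = ReferenceSequence("demo", "TTGAACGGATCGTTCA" + "TGCA" * 10 + "GAACTT")
sites = scan_motifs(ref)
print(f"{len(sites)} motif sites on a {len(ref)} bp reference:")
for s in sites:
    print(f"  start={s.start:2d} motif={s.forward_motif} "
          f"plus_cleavage={s.plus_cleavage:2d} "
          f"minus_cleavage={s.minus_cleavage:2d}")

controls = sample_control_sites(ref, sites, n=3, seed=1)
print("control (non-motif) positions for background estimation:",
      [c.position for c in controls])
# Each line is one bistranded candidate locus; cleavage points are where
# iodine-cleaved reads are expected to start on each strand.
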