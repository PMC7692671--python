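# Methods

## The observable

Phosphorothioate (PT) modification in enterobacteria sits on both strands
of GAAC/GTTC loci (GpsAAC paired with GpsTTC).  Iodine cleaves a modified
strand immediately 3′ of the PT-bearing G.  For a forward-strand GAAC with
first base at 0-based coordinate `s`, the reverse strand reads GTTC with
its G at `s+3`; the downstream-fragment 5′ ends after cleavage are
therefore `s+1` on the plus strand (reads begin `AAC…`) and `s+2` on the
minus strand (reads begin `TTC…`).  The same arithmetic holds for a
forward GTTC.  All ptseq coordinates are 0-based, half-open; BED output
follows the same convention.

At a candidate site every aligned read falls into one of three classes:
its 5′ end sits at a cleavage point (evidence of a cleaved, hence
modified, molecule); it fully contains the intact 4-mer with its 5′ end
elsewhere (a *spanning* read, evidence of an uncleaved molecule); or it is
uninformative.  "Spanning" requires full containment of the 4-mer — a read
merely overlapping the cleavage point says nothing about whether the site
was intact on that molecule.

## Callers

**ICDS (qualitative).**  Reads carrying the ligated duplex tag at their 5′
end derive from iodine-cleaved molecules.  After tag detection/trimming, a
site is called modified when its tagged-end count (plus-strand ends at
`s+1` plus minus-strand ends at `s+2`, summed per bistranded locus) is
strictly greater than `min_reads` (default 50).  The rule operates on raw
counts and is therefore sequencing-depth dependent; ptseq applies it as
stated and reports counts so users can judge depth.  A `--per-strand` view
is available through the pileup API (query each cleavage point
separately).

**PT-IC-Seq (quantitative).**  The per-site modification frequency is
`f̂ = n_end / (n_end + n_span)`, undefined (reported as missing, never
passing) when both counts are zero.  Under the generative model below with
full cleavage (c = 1), `f̂` estimates the per-molecule modification
probability f; with partial cleavage it estimates f·c.

**Control threshold.**  Sonication deposits fragment starts everywhere, so
unmodified sites show a nonzero `f̂`.  Background is estimated at `n`
random control positions (default 10) chosen so that no motif 4-mer
overlaps `[p−3, p+4)`, each evaluated with the same ends/spanning
machinery via pseudo-cleavage points at `p+1`/`p+2`.  The decision rule is

```
threshold = mean(control f̂)  +  k · sqrt(mean·(1−mean)/n̄)
```

with `n̄` the mean control coverage and `k = 6` by default; `k = 0`
reproduces the plain control-average rule.  The model-based binomial
standard error is used as the scale rather than the empirical sd of the
controls because a handful of control sites cannot estimate their own
spread reliably (the sd of a sample sd at n = 10 is ~24% of σ); the
empirical sd is still reported.  The choice k = 6 is a genome-wide
multiplicity argument: with shear-background end counts approximately
Poisson with mean `2Mu` (M molecules, u = 1/mean-fragment-length) and on
the order of 10³–10⁴ candidate motif sites per megabase, holding the
expected number of background crossings below ~0.05 requires the threshold
near the 1−10⁻⁴ Poisson quantile, which sits about six model-SEs above the
mean at typical coverage.  A site passes only if its frequency is defined
and **strictly** greater than the threshold; "more than 50 reads" and
"above the threshold" are both read strictly, so boundary values fail.

With ~10 controls the threshold estimate itself carries ~25% relative
noise (its background information is a Poisson total of `2Mu·n̄·n/(n̄)`
≈ 16 end counts at default coverage).  Users quantifying genomes with many
candidate sites at modest depth should raise `n_controls`; the default
stays at 10, the protocol's number.

## Read QC

Rules, applied in order per read: adapter clipping (longest 3′-terminal
segment matching an adapter prefix, minimum overlap 8, one mismatch per 10
bases); removal of leading non-A/C/G/T symbols; in ICDS mode, tag
detection at the 5′ end (≤1 substitution by default, no indels) and
trimming; 3′ trimming while the terminal base is below Q20; then removal
of reads with >10% N calls (strict) or <25 bp (strict).  A read emptied by
a trimming step is removed under that step's reason, so the report
partitions the input exactly.  Quality trimming is the simple
terminal-base rule; a sliding-window mode is deliberately not the default
since nothing in the assay requires it.  The optional removal of one A/T
base after the tag (an A-tailing ligation artifact) is off by default:
genuine cleavage-derived inserts begin with AAC/TTC, so a lone artifact
base is indistinguishable from signal and unconditional removal would
corrupt every true cleavage 5′ end.

## The simulator

Per double-stranded genome copy: (1) each planted site is modified with
probability f, on both strands together by default (fully coupled
bistranded model; `independent_strands` relaxes this); (2) each modified
strand is cut at its cleavage point with probability c (default 1 —
iodine cleavage of PT is near-quantitative); (3) remaining strand segments
are sheared into fragments with lengths drawn sequentially from U{150..350}
(the protocol's sonication range), the terminal remainder kept as its own
fragment, so fragment starts form an exact renewal process with mean step
250 bp; (4) each fragment yields one single-end read from its 5′ end,
truncated to `read_length`, with independent substitution errors (default
10⁻³, quality Q37/Q11 for correct/substituted calls) and N calls (5×10⁻⁴,
Q2).  ICDS mode prepends the tag to cleavage-derived reads only and emits
only those (enrichment modelled as selection, not amplification — the
caller thresholds counts and no duplication model is claimed).  PCR
duplicates, indels, GC-biased coverage and paired-end structure are not
modelled.

`read_length` defaults to 350 = the maximum fragment length, so each read
observes its entire fragment.  This mimics the effective fragment-level
observation of short-insert paired-end sequencing and makes
`ends/(ends+spanning)` an unbiased estimator of f·c; with reads shorter
than fragments, spanning events are undercounted and the estimator is
biased upward — a real-data caveat for single-end libraries with long
inserts.

Under this model the analytic background frequency at a control site is

```
f_bg = u / (u + (1−u)³),   u = 1/250 ≈ 0.004
```

(end rate u per strand; the 4-mer survives intact on a strand unless one
of its three internal junctions is hit).  This value is exposed as
`expected_shear_background()` and the test suite checks the simulator and
pipeline against it.

Because the default model couples the two strands of a molecule, the
independent sampling unit for a site's frequency is the molecule, not the
read: with M molecules and c = 1, `f̂ ≈ Binomial(M, f)/M` even though
`n_end + n_span ≈ 2M`.  Statistical checks in the tests use M as the
binomial n accordingly.

What passing simulation tests do **not** show about real data: the
simulator has no coverage bias, no duplicates, no mapping ambiguity beyond
exact repeats, and its error model is substitution-only; real libraries
will show broader site-to-site dispersion than the binomial model.

## The fixture mapper

`naive_align` places reads by exact full-length match (20-mer seed,
verify, both orientations), dropping unplaced and multiply-placed reads.
It exists so the pipeline runs end to end without an external aligner.
Reads carrying any sequencing error do not align and are dropped —
uniformly with respect to position, so frequency estimates are unbiased
but effective depth shrinks by ≈ read_length × error rate.  Production
use should supply SAM/BAM from a real aligner; ptseq consumes primary
mapped records, taking strand from the reverse flag and the end from CIGAR
reference consumption.

## LC-MS/MS arithmetic

Calibration is unweighted ordinary least squares of response on
concentration with a free intercept (the protocol specifies the axes but
no weighting), r² reported, inversion warned outside the fitted response
range.  Mononucleoside concentrations (ng/µL) convert to moles via
per-species deoxyribonucleoside molecular weights (dC 227.22, dT 242.23
g/mol; overridable constants, since the convention is not fixed by the
protocol).  PT density uses duplex base-pairing (#A = #T, #C = #G):

```
density_X = 10⁶ · mol_X / (2·(mol_C + mol_T))    X ∈ {GpsA, GpsT}
```

which is invariant under uniform scaling of all mole quantities.
Replicate aggregation (mean ± sd over biological replicates) is left to
the reporting layer.

## Numerical and design notes

* Strict inequalities everywhere a boundary must be resolved (>50 reads,
  > threshold, >10% N, <25 bp); ties therefore fail closed.
* Ambiguity codes in references are masked to N and can never match a
  motif; reads with N at the decisive positions simply fail tag/alignment
  matching.
* Overlapping motif occurrences are reported independently; no merging.
* Circular references: motif windows wrapping the origin are scanned when
  the contig is flagged circular (cleavage coordinates taken mod L);
  wrap-around *spanning* queries are not implemented — no alignment in the
  data model wraps, and the simulator emits linear molecules.  Analyses of
  circular genomes lose at most the few sites within 3 bp of the chosen
  origin.
* Duplicate reads are not removed (the assay protocol performs no
  deduplication); mapping-quality filtering defaults off.
* Control sites are resampled per run unless a seed is pinned; every CLI
  run writes its seeds to a manifest.
* Map binning follows the published ring layout: ICDS tagged-end counts in
  (50, 1050], (1050, 2050], (2050, 3050], (3050, ∞); PT-IC-Seq frequencies
  in [5%, 15%), [15%, 25%), [25%, 35%].  Out-of-range values are flagged,
  never silently dropped.
* Problem sizes in the test suite (50 kb genomes, 200 molecules, ≤20
  seeds per property) are chosen so the statistical checks have meaningful
  power while the whole suite stays desk-scale.
* Single-stranded PT systems are out of scope: the bistranded GAAC/GTTC
  geometry is built into the site model.
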