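# Methods

## The screen being modelled

`cisscout` analyses retroviral insertional-mutagenesis screens of the kind
used to tag candidate cancer genes in mice: a murine leukemia virus (MuLV)
integrates semi-randomly into tumor-precursor genomes; insertions that
deregulate a growth-promoting gene are clonally selected, so independent
tumors accumulate insertions at the same loci far more often than chance
allows.  Such loci — common insertion sites (CIS) — are detected
statistically.  Integration sites are recovered by linker-mediated PCR:
tumor DNA is digested with MseI (TTAA) or NlaIII (CATG), ligated to
double-stranded adaptors, digested with EcoRV (GATATC) to destroy
provirus-internal fragments, and amplified by two rounds of nested PCR
between an LTR primer and an adaptor primer.  A sequencing read therefore
runs `LTR-primer → host flank → adaptor`.

The package covers the computable arc of such a screen: amplicon-read
processing, per-tumor insertion cataloging, Monte Carlo CIS calling,
CIS-to-gene annotation with an orientation-based expression-effect
prediction, and a survival/dependency triage of candidate genes.  Every
stage can be exercised on fully truth-labelled synthetic data from
`cisscout.simgen`.

## The CIS statistic

### Scan reduction

Windows are anchored at observed insertion positions: every insertion x
opens a candidate window [x, x+w).  A set of insertions "fits" a window of
size w iff `last − first + 1 ≤ w`.  This is the standard scan-statistic
reduction — a cluster qualifies through its span, not through a fixed
genomic grid — and it makes the statistic sensitive to both the number of
insertions and the distances between them.

### Monte Carlo calibration

For a catalog of n insertions, each of M null iterations (default 1,000)
places n positions uniformly over the genome and records, per window size w,
the genome-wide maximum anchored-window count.  The threshold k_w is the
smallest k whose empirical null probability `P(max ≥ k)` falls below alpha
(default 0.05), floored at 5 insertions.  Because the null statistic is the
genome-wide maximum, significance is family-wise (FWER) across the whole
genome at each window size.  Four window sizes (10/20/30/40 kb, spanning the
size range of an average mouse transcriptional unit) are scanned; a locus
significant at several sizes is reported once, at the smallest.

Scanning four window sizes means four marginally-calibrated FWER tests per
cohort.  Their maxima are computed from the same points and are strongly
positively correlated, and the discreteness of counts leaves each marginal
test below its nominal level, so the union stays near alpha; the acceptance
experiment measures the realized family-wise rate directly (~0.03–0.06
across seeds at screen density, within two Monte Carlo standard errors of
alpha).

An optional motif-constrained null restricts placements to within a
configurable distance of a restriction site, reflecting library
accessibility; the uniform null is the default for transparency.

The calibration consumes exactly one block of n random integers per
iteration from a seeded generator, so an independent re-simulation can
share the stream — the test suite exploits this to check the null maxima
against an O(n²) brute-force re-computation, value for value.

### The per-tumor cap

A tumor's clone can re-integrate locally ("local hopping"), producing many
nearby insertions that are not independent selection events.  Each tumor
therefore contributes at most 2 insertions (configurable) to a window's
qualifying tally.  The cap down-weights clonal clusters without discarding
genuinely multi-tumor loci; a stricter mode (`disqualify_clonal`) that
discards any window containing more than the cap from one tumor is
available by flag.

### Reported intervals and ranking

Within an overlapping group of qualifying windows, the reported interval is
the *minimal* span whose capped tally reaches k_w (ties: more insertions,
then leftmost) — the minimum genomic region supporting significance — so
every emitted interval is at most one window wide (≤ 40 kb at defaults).
The call's `n_insertions`, used for frequency ranking, counts the whole
supporting cluster, not just the minimal interval: a heavily hit locus
should outrank a sparse one even though both report tight intervals.
Empirical p-values use (b+1)/(M+1) smoothing and so are never exactly zero.
Ranks are a total order: count desc, then p-value, interval width, genomic
position.

## Read processing

Exact substring matching deliberately replaces read alignment: synthetic
genomes are unambiguous, re-implementing an aligner is out of scope, and
real data mapped by any external aligner enters via 6-column BED
(`import_mapped_bed`).  Consequences to be aware of:

* a single substitution error in the flank makes a read unmappable
  (`unmapped`), so at the default simulated error rate (0.002/base) roughly
  a quarter of 150 bp reads are lost — realistic pipelines would align
  mismatch-tolerantly; error-free simulations round-trip 100%;
* flanks shorter than `min_flank` (20 bp) or occurring more than once
  genome-wide are rejected (`short_flank`, `multimapped`); at 4-bp motif
  densities ~12% of junctions sit within 16 bp of a cut site and are
  intrinsically unrecoverable.

The LTR nested primer must appear at the read start (offset ≤ 2, ≤ 2
mismatches; smallest offset wins).  The adaptor — the reverse complement of
the nested adaptor primer — is removed on a full match (≤ 1 mismatch)
anywhere, else on the longest 3'-terminal match against the adaptor prefix;
below 6 bp of overlap only exact matches are trimmed.  Over-trimming a
genomic suffix is harmless (the junction is the flank *start*), while an
untrimmed adaptor remnant would break exact mapping, so suffix trimming is
deliberately aggressive.

The junction coordinate is the first host base 3' of the LTR end, 0-based
internally and BED half-open externally.  For a minus-strand provirus the
read runs leftward along the reference, so the junction is the *end* of the
reverse-complement match.

## Catalog

Within one (tumor, chromosome, strand) group, sites whose positions chain
within a 5 bp tolerance merge to the support-weighted modal position (ties
to the smaller coordinate); read support sums, specimen provenance is
retained.  The tolerance absorbs end-trimming jitter and PCR duplicates
without merging distinct integrations at screen densities.  Strand is part
of the key — coincident opposite-strand sites are distinct proviruses — so
the "one site per tumor per position" uniqueness holds per strand.
Specimens of one mouse share a tumor ID: the clonality rule operates at the
tumor level, and multi-specimen recurrence of one integration is evidence
about sampling, not independence.

## Gene assignment and effect prediction

A CIS maps to every gene model it overlaps, else to the nearest gene within
100 kb (configurable).  The predicted expression effect follows standard
MuLV enhancer/promoter-insertion logic, implemented as named predicates on
configurable windows (defaults 10 kb): upstream of the TSS or in the first
exon, either orientation → increased; elsewhere in the body → decreased;
within the downstream window → increased; otherwise no vote.  The call-level
prediction is the majority vote of its insertions, ties → ambiguous.  These
rules are a field convention rather than a measurement, which is why they
are data, not code.

## Survival and dependency triage

Patients are split into top/bottom expression quartiles (⌊N/4⌋ each, ties
broken by patient ID for determinism) and compared by a two-group log-rank
test; the hazard ratio is estimated from the log-rank tables as
(O_a/E_a)/(O_b/E_b) rather than by fitting a proportional-hazards model —
closed-form and sufficient for a pass/fail screen; a model-based HR is a
documented extension point.  Survival pass requires p < alpha *and*
direction consistency with the predicted effect (increased → HR > 1), so
the null pass rate is alpha/2, not alpha.  Dependency pass requires the
median cell-line dependency score ≤ −0.5 (more negative = more essential);
the threshold, like the upstream portals' exact criteria, is a documented
assumption.  Literature and wet-lab filters are represented only as
pass-through annotation columns.

## The synthetic-data generator

Defaults encode the screen's scale: 21 tumor-bearing mice × 8 specimens =
168 specimens; 268 background insertions per specimen ≈ 45,000 integration
events; clinical cohorts of 776 patients giving expression quartiles of
194.  Genomes are i.i.d. uniform A/C/G/T, so each 4-bp motif occurs at
~1/256 per position and restriction-fragment lengths are realistic; literal
sequences can be injected for fixtures.  Background insertions are uniform;
spiked CIS clusters have configurable width, size, per-tumor multiplicity
and strand bias, and full truth labels are retained end to end.

EcoRV emulation: provirus-internal fragments (the enzyme's purpose) are
simply never emitted; host-side fragments containing GATATC are excluded
too, since digestion would separate their LTR end from their adaptor end.
One read per recoverable site per specimen is emitted by default (PCR
duplication by an optional multiplier); a site with no cut site within
`max_flank` (2 kb) emits nothing and is logged.

Survival times are exponential with a patient's hazard equal to a baseline
(0.02/month — median ~35 months, typical of myeloma cohorts) multiplied by
the configured hazard ratio for each gene in whose top expression quartile
the patient falls; censoring is independent exponential, calibrated so a
baseline-hazard patient is censored with the configured probability (0.3
default).  Dependency scores are the configured per-gene value plus
Gaussian noise across simulated cell lines.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real screens: non-uniform MuLV integration preference
(TSS/enhancer bias), mappability and repeat structure of a real genome,
chimeric/artifact reads, indel or quality-dependent errors, cross-sample
contamination, T-lineage tumors, and correlated expression between genes.

## Problem sizes and numerical choices

Simulation experiments scale the screen to desk-sized genomes at the
screen's insertion *density* (18/Mb): the type-I-error experiment uses 500
null cohorts of ~1,850 insertions on 100 Mb; spike-recovery uses 100
replicates on 20 Mb; calibrations use 1,000 Monte Carlo iterations.  These
sizes put Monte Carlo standard errors well below the effect sizes being
checked while keeping any single experiment under a minute or two of CPU.
All stage seeds derive from one global seed by fixed offsets; reruns are
byte-identical.  Degenerate inputs are defined, not special-cased: an empty
catalog yields no calls, n = 0 calibration returns the floor thresholds,
zero-event survival tables return p = 1 with the hazard ratio flagged
undefined.

## Known limitations

* Exact-match mapping is a stand-in for alignment; error tolerance lives in
  primer trimming only.
* The uniform null understates clustering under real integration-site
  preferences; the motif-constrained null is a first step, not a fix.
* The O/E hazard ratio is biased toward 1 relative to a Cox estimate when
  hazards are non-proportional.
* Effect-direction rules ignore enhancer orientation dependence and
  long-range interactions; they are majority votes over coarse geometry.
* Cross-window collapsing keeps the smallest significant window; a locus
  with genuinely nested sub-clusters is reported once.
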