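# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the order the pipeline runs them.

## Coordinate conventions

All intervals are 0-based half-open (BED). 1-based inputs (VCF-style
positions) are converted at the I/O boundary. Strand is carried on
intervals but ignored by interval algebra; only motif operations interpret
it. Two gap conventions coexist deliberately: stitching/merging joins
intervals whose gap is **≤** the threshold (so peaks exactly 12.5 kb apart
stitch), while homotypic clustering requires consecutive gaps **strictly
<** the threshold (instances exactly 75 bp apart split). Nearest-distance
ties resolve to the leftmost reference; queries on chromosomes absent from
the reference return `inf` ("unreachable"). Multi-way intersection uses
base-level semantics, which makes the result independent of the order the
tracks are given in; reciprocal-overlap semantics were considered and
rejected because no overlap fraction is canonical for four heterogeneous
assays.

## Differential expression

The caller avoids a parametric dispersion model on purpose: with two
replicates per condition a negative-binomial dispersion estimate is
fragile, so significance comes from the exact conditional binomial
rate-ratio test — given the feature's total count, the infected share is
binomial with probability equal to the infected library share. Fold change
is computed separately, on library-size-normalized replicate means with a
0.5 pseudocount per condition (so a feature at counts 10 vs 40 reports
FC = 40.5/10.5 ≈ 3.86, not 4.0). Benjamini–Hochberg adjustment runs across
features; both raw and adjusted P are emitted because the upstream
threshold convention ("P < 0.05" with FC ≥ 2) does not say which is meant.
Calls use the adjusted value. The same caller with `fc_min=1.4` serves for
transposable-element family tables; TMM normalization is replaced by plain
library-size normalization (multimapper-aware quantification is out of
scope).

The test is exact under Poisson sampling and conservative in the
two-sided "minlike" form; under strong overdispersion it is
anti-conservative, which the BH gate largely absorbs at these problem
sizes (measured null call rate ≈ 0.006 at dispersion 0.05).

Responsiveness gates partition [2, ∞): C/I at FC ≥ 16, C/II at
4 ≤ FC < 16, C/III at 2 ≤ FC < 4 — boundaries inclusive at the lower edge.

## STARR activity

Reporter counts are compared on raw scale (the assay's own convention),
fold change = infected/mock with a pseudocount of 1 only when mock = 0
(flagged). Significance is the exact binomial test of the infected count
against the infected-library share of the element total; the share
defaults to the summed counts of each arm, but callers that know the
libraries are depth-matched (the synthetic pipeline) pass equal shares —
deriving shares from summed counts would fold a planted active fraction
into the null. The call gate is FC ≥ 1.44, raw P < 0.05, no multiplicity
adjustment (the element set is a pre-selected candidate pool, and the
upstream convention is a raw threshold; a BH switch exists). Strata are
[1.4, 2), [2, 10), [10, ∞); the stratum floor (1.4) sitting below the call
gate (1.44) is kept as printed upstream rather than reconciled.

## Super-enhancer calling

Peaks fully contained in TSS ± 2 kb are removed before stitching (a peak
merely overlapping a promoter window survives). Remaining peaks merge at
gaps ≤ 12.5 kb. Region signal is the base-weighted sum of
(marker − input) scores, floored at zero, divided by a nominal per-million
factor — read-level RPM requires alignments, which are out of scope, so
scores arrive pre-normalized. Regions are ranked ascending; both axes of
the rank curve are scaled to [0, 1] and the cutoff is the left endpoint of
the first finite-difference segment with slope > 1, that rank included
among the SEs. On the analytic curve y = x² this reproduces the slope-1
tangent at x = 0.5 and flags exactly the upper half of an even-length
curve. One consequence: when the curve has a single sharp jump, the last
region below the jump is included, so one borderline region can enter the
SE set. A perfectly flat curve yields no SEs.

Dynamics use ≥ 1 bp cross-state overlap (configurable): 0 h-only → pdSE,
overlapping → pmSE (counted once, from the naive side), 6 h-only → viSE.
Gene assignment requires |TSS − SE center| ≤ 0.5 Mb (inclusive) and
replicate-mean normalized expression ≥ 10 in the state examined.
Element localization gives SE precedence over tE; anything else is safG.

## Motif machinery

IUPAC consensus matching is exact degenerate-code matching; PWM scanning
scores log2-odds against a uniform background with a 0.5 pseudocount per
cell. The default PWM threshold is the smallest score whose uniform-
background tail probability is ≤ 1e-5, computed by exact dynamic-
programming convolution of the per-column score distributions (identical
in result to enumerating all sequences, and tractable at any length;
scores are binned at 1e-4). Overlap resolution is greedy: by position,
then higher score, then plus strand — deterministic by construction.
Minus-strand hits are reported in plus coordinates.

Cluster windows measure span from the first matched base to the last.
IR-HCTFBS: ≥ 3 perfect sites in ≤ 400 bp (core), else > 10 AAAG half
sites in ≤ 1000 bp (both thresholds configurable; the upstream convention
wavers between "> 10" and "10–43 within 1 kb" — strict > 10 in 1 kb is
implemented). κBR-HCTFBS: ≥ 3 perfect sites in ≤ 400 bp, or 4–14
degenerate GGGNNNNNCC sites (both strands) in ≤ 1300 bp, treated as a hard
range: a denser window is reported out-of-range and does not call. GGRR
half sites are counted and annotated but never trigger a call — no count
threshold for them is established. Note the AAAG half-site rule is only
meaningful on element-sized input: random DNA carries one AAAG per ~256 bp
per strand, so a megabase of background trivially contains qualifying
windows; the caller is meant for elements of a few hundred bp.

Syntax of consecutive perfect-site pairs: same strand → Head-to-Tail;
+ then − (directions facing) → Head-to-Head; − then + → Tail-to-Tail;
element label is the majority over pairs, "mixed" on ties.

Genome coverage of the 25-bp clustered-IRF3 consensus is
100 · n · 25 / L with nonoverlapping instances; IRHADs are runs of ≥ 3
instances with gaps < 75 bp.

## Proximity resampling

Foreground and background nearest-TSS distances are compared by the
two-sided Mann–Whitney test (normal approximation with tie and continuity
corrections — 10⁴ repetitions rule out exact enumeration); sampling is
without replacement (the upstream choice is unstated; without replacement
matches sampling distinct genomic bins). Success = inner P ≤ 0.05; the
overall statistic is the exact one-sided binomial tail of the success
count against 0.5, i.e. strongly significant only when the foreground
beats most resamples. The seed fans out to per-repetition substreams
(SeedSequence spawning), so runs are reproducible and order-independent.
The background pool is the genome tiled into 300-bp bins minus blacklist,
foreground, and source peak sets. Distance curves accumulate foreground
counts over the first 10 kb in 300-bp steps.

## Repeats and conservation

TR evidence: any TRF record, or RepeatMasker Simple_repeat /
Low_complexity / Satellite. DR evidence: LINE / SINE / LTR / DNA. Both →
c(T:D)R; neither → nonrepetitive; unknown RepeatMasker classes are an
error naming the class. phyloP averaging rescales every element to 500
bins (elements shorter than 500 bp repeat source bases; longer elements
average within bins), with uncovered bases contributing 0; constant tracks
are exactly invariant under the rescaling. Evolutionary gating cascades
outward — any beyond-mammal hit wins, then non-primate mammal, then
non-great-ape primate, else HHPe-primates — where a species "hits" iff its
conserved stretch is > 100 bp **and** similarity > 60% (both strict). The
great-ape/primate boundary for HHPe is configuration data
(`species_groups`), not code; similarity is an input column, since
multi-genome alignment is out of scope.

## Synthetic data

The generator emulates the study's conditions: two states (0 h naive, 6 h
infected), two replicates, eight assays, a 1-Mb two-chromosome genome.
Counts are negative binomial (variance m + αm², α = 0.05 — a typical bulk
RNA-seq dispersion) for genes; STARR counts default to Poisson because
they model technical replicates of one transfected pool, which is also
the sampling model under which the conditional binomial test is exact
(an NB dispersion knob exists for robustness experiments). Planted
upregulated genes draw log-uniform fold changes within their cluster's
band; active STARR elements draw fold changes from the low/mid/high
strata at proportions 16/82/2%.

Planted loci are constructed to be identifiable: super-enhancer loci are
five constituents spaced 2–8 kb, separated from every other peak by a
13-kb buffer (beyond stitch reach), and gene TSSs avoid SE loci ± 2.5 kb
so promoter exclusion cannot split a planted run. Motif clusters plant
three unambiguous perfect sites (ISRE-like `GGAAAGTGAAAG`, κB decamer
`GGGACTTTCC`) within ≤ 400 bp; isolated and clustered cIR-motif instances
are planted with IUPAC codes resolved at random. Repeat segments cycle
through the RepeatMasker class vocabulary (tandem ones also listed as TRF
records); a conserved subset of planted clusters carries conservation
+2.0 over a 0.0 background — clean separation by design, for gate tests.
Everything derives from `(seed, stage-tag)` substreams, so the three
generators are independently deterministic and byte-identical under a
fixed seed, and a JSON ledger records all planted truth.

What the generator does **not** emulate: read-level noise, GC and
mappability bias, correlated replicates, fragmented peak calls, repeat
sequences with realistic divergence, or conservation scores with
phylogenetic structure. Passing recovery tests therefore demonstrates the
correctness and calibration of the procedures under their stated
assumptions, not their performance on real sequencing data.

## Problem sizes

Benchmarks and the acceptance script run at desk scale, chosen so the full
suite completes in about a minute on one CPU: calibration uses 200 seeds ×
60 null features; recovery 20–25 seeds; the proximity null 50 runs × 1,000
resamples (the analysis-scale default remains 10,000); the end-to-end
pipeline runs one 1-Mb genome. Rates at these sizes carry Monte-Carlo
standard errors of ~0.2–2 percentage points, which the acceptance margins
accommodate.

## Known limitations

- The DEG/SHAe tests assume conditional-binomial sampling; strongly
  overdispersed element counts need the BH switch or an external NB test.
- The inflection cutoff can admit one borderline region at a sharp
  rank-curve jump (see above).
- `signal_matrix` takes the last-written score where scored intervals
  overlap; supply disjoint (bedGraph-style) tracks.
- Fisher overlap treats bins as exchangeable; genomic autocorrelation is
  not modelled.
- The pipeline orchestrates synthetic inputs end-to-end; real-data use is
  through the per-stage CLI subcommands and library functions.
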