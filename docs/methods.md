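# Methods

This note documents the models implemented in `cisplice`, the conventions
and numerical choices behind them, the design of the synthetic validation
genome, and what the passing test suite does and does not demonstrate.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open; GTF input/output converts
from/to 1-based inclusive at the boundary, so length arithmetic is always
`end − start`. Every sequence-derived feature is computed on the sense
strand (5'→3' of the transcript): the sequence accessor reverse-complements
minus-strand queries, and transcription order (exon ranks, upstream /
downstream flanks, relative position) is mirrored for minus-strand genes.

## Event catalogue

Events are defined purely combinatorially over a gene's transcript exon
chains, with exon identity meaning exact `(start, end)` equality:

* **constitutive** exon/intron — present in every transcript;
* **EC** — internal exon present in ≥1 but not all transcripts;
* **IR** — intron of ≥1 transcript fully contained in an exon of another
  transcript of the same gene;
* **ALT5SS / ALT3SS** — two exons sharing exactly one boundary; which
  splice site varies is resolved relative to the strand, and the event's
  variable region is the differential segment between the two boundaries;
* **AFE / ALE** — transcript-initial/terminal exons (in transcription
  order) that differ between transcripts, are not internal to any
  transcript, and do not overlap their alternative partner;
* **MXE** — two internal, non-overlapping exons that never co-occur, where
  every transcript carries exactly one of the pair (without attested
  exclusivity the pair stays two ECs — a deliberately conservative rule).

A supplied differential event resolves by exact-coordinate match to the
catalogue; a region equal to a constitutive intron is called novel IR
(`annotated=False`); everything else is UNKNOWN and retained in all outputs
(the unannotated class is analytically interesting, not noise). How an
upstream database splits "annotated" from "novel" events is generally
proprietary; exact-coordinate matching is this package's own documented
convention.

Exons made "alternative" only as a side effect of an intron-retaining or
single-exon isoform (e.g. the flanking exons of a retained intron) may
satisfy the EC definition; they are catalogued as such, which slightly
enlarges the reference cassette pool with sequence-typical exons and has no
effect on the comparative statistics.

## Splice-site model

First-order PWM log-odds in bits (not a maximum-entropy model): donor 9 nt
(3 exonic + 6 intronic), acceptor 23 nt (20 intronic + 3 exonic). Foreground
probabilities are trained on the constitutive junctions of the supplied
annotation with pseudocount 1 per base (hard error below 50 junctions —
supply a PWM file instead); the background is the genome-wide base
frequency over gene spans. `N` bases contribute 0 bits at their position.
Training from the input annotation keeps the package download-free and
self-consistent; externally trained matrices can be loaded from TSV
(columns A, C, G, T; one row per position).

## Branchpoint and polypyrimidine tract

The branchpoint model is a shipped heptamer probability matrix
(`data/branchpoint_pwm.tsv`) with the branch adenosine at position 6,
modelled on the classical TACTAAC branch consensus. The matrix is
deliberately strong — position probabilities 0.90–0.96 — so that
branchpoint placement is well determined on synthetic sequence; real human
branchpoints are more degenerate, and users analysing real genomes are
expected to override the file with a softer model. The search window is
18–100 nt upstream of the intron 3' end (branchpoints closer than ~18 nt
are sterically implausible); ties resolve to the 3'-most maximum so the
result is deterministic; introns shorter than 25 nt yield missing values.
`bp_distance = intron_length − (branch A index + 1)`.

The PPT is searched between the branch A (exclusive) and the acceptor AG
dinucleotide (exclusive): its length is the longest contiguous C/T run and
its score sums T=1.0 / C=0.5 over that run — a common heuristic chosen for
transparency; among equal-length runs the higher-scoring, more 3' run wins.

## Per-event feature panel

For exonic events the 3'ss is the acceptor of the upstream intron, the 5'ss
the donor of the downstream intron, branchpoint/PPT come from the upstream
intron, and the flanking context is intronic. For intronic events (IR) the
scores are the intron's own sites, branchpoint/PPT come from the intron,
and the flanking context is exonic. GC is `(G+C)/(A+C+G+T)` with N excluded
from both sides; the event region and each flank are reported separately.
`rel_position` maps the region midpoint to the fraction of the gene span,
oriented 5'→3' (minus-strand genes mirrored). Gene architecture (length,
mean intron length, intron/exon length ratio, intronless flag) is computed
on the representative transcript — the one with the greatest total exonic
length, ties broken by transcript id. Missing features propagate as NaN and
are excluded pairwise from statistics.

## Statistics

* **Welch's t** with Satterthwaite degrees of freedom (not rounded),
  two-sided p from the t distribution. Two zero-variance samples with equal
  means give t=0, p=1; with unequal means the comparison is degenerate and
  raises.
* **Fisher exact**, two-sided (sum of hypergeometric outcomes no more
  probable than the observed table), for pattern enrichment of regulated
  events against the annotated catalogue and for intronless-fraction
  contrasts. The enrichment output flags the test used: published analyses
  of this kind sometimes cite a "modified" Fisher test without defining the
  modification, and this package deliberately implements the standard test.
* **Benjamini–Hochberg** applied once across each result set; raw p-values
  are always emitted alongside.
* Positional distributions use 10 equal bins of [0,1], last bin closed,
  densities normalised to sum 1.
* Reference groups (not-regulated cassettes, annotated IR, constitutive
  exons/introns) are down-sampled to 500 with a seeded RNG; this is the
  only stochastic step of the analysis, so a fixed seed makes the whole
  pipeline byte-deterministic.

Gene-level analyses partition the expression universe (genes with baseline
log2 FPKM ≥ 0 by default; the floor is configurable because "expressed" has
no universal definition) into GE-only / AS-only / GE&AS / unaffected, where
"unaffected" — the reference for expression and architecture comparisons —
means *neither* change, not merely "not in the regulated set". The gene
class table takes the full expression table plus the event table and
applies the significance filter internally, since the unaffected class is
undefinable from pre-filtered records alone.

## Synthetic genome generator

The generator emulates the statistical structure the analysis assumes:
multi-isoform gene models (cassette, retained-intron, AFE/ALE, ALT5SS/
ALT3SS, MXE hosts, plus single-transcript and intronless genes, roughly
half on each strand) whose every junction carries sampled donor/acceptor
sites, a planted branchpoint at a controlled distance, and a
pyrimidine-rich tract. Defaults define the study conditions recovered by
the validation harness:

| parameter | default | notes |
|---|---|---|
| genes | 1,300 | 200 up-EC, 200 down-EC, 500 reference-EC, 200 up-IR hosts, 60 annotated-IR hosts, 10 hosts per minor pattern, ~5% intronless |
| exon length | log-normal, median 130 nt, σ=0.35, clipped [60, 400] | |
| intron length | log-normal, median 250 nt, σ=0.55, clipped [90, 3000] | floor fits donor+BP+PPT+acceptor |
| GC | exon 0.52, intron 0.42, intergenic 0.40 | |
| branchpoint distance | N(35, 6) nt, clipped [21, 60] | |
| up-EC effect | 3'ss −2 bits | |
| down-EC effect | 3'ss +1 bit, BP −10 nt, GC −0.08 | |
| up-IR effect | intron length ×0.5, position ~ Beta(3,1) | |
| expression | baseline N(3.0, 1.8) log2 FPKM; splicing-regulated hosts +1; 150 GE-up (50% from the intronless pool) and 150 GE-down at \|log2FC\| ≥ 1 | |

Splice-site shifts are realized by sampling sites from a temperature-tilted
PWM. The tilt is calibrated analytically (bisection on the inverse
temperature, exact expectation — no Monte-Carlo error) against the scoring
matrix the analysis will effectively apply: the generator matrix smoothed
as if trained on the expected number of constitutive junctions, against the
expected genome background. This makes the injected effect sizes live in
the same units the pipeline measures; the residual discrepancy between the
requested and the measured mean shift is below ~0.05 bits, well inside the
±0.3 replicate spread at n=200 vs 500.

Which intron of an up-IR host is "retained" is chosen by snapping a Beta
draw to the nearest intron *rank* (not genomic midpoint): the rank grid is
length-independent, so a Beta(1,1) draw selects every intron with equal
probability and the null generator is free of length bias. Regulated IR is
injected on constitutive introns of single-transcript genes, so those
events are (by design) absent from the catalogue and exercise the novel-IR
path; annotated IR comes from dedicated two-isoform hosts.

The differential tables encode significance directly: regulated events draw
p ≤ 0.04 and fold-change ≥ 2, background rows fail at least one filter
condition, so ground truth and filter output coincide exactly. One global
RNG stream seeded from the call makes identical (spec, seed) pairs
byte-identical on disk. The `null_spec()` variant zeroes every effect while
keeping the structure: "regulated" labels then mark random background
draws, which is the type-I-error harness. Note that the null generator
keeps the regulated sets' *pattern composition* fixed (it nulls features,
not pattern frequencies), so pattern-enrichment p-values are not expected
to be uniform under it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing noise and read-level quantification
(the differential tables are taken as given), positional base correlation
beyond the planted motifs (background is i.i.d. within compartments),
degenerate human branchpoints (see above), overlapping genes, alternative
promoters with shared internal structure, isoform expression levels, and
any coupling between features (each effect is injected independently).
Recovery on this genome demonstrates that the measurement and inference
chain is unbiased and calibrated, not that effects of this size exist in
any particular dataset.

## Problem sizes and runtimes

The validation harness runs 50 seeded replicates of the full
generate→analyse cycle for effect recovery (p < 0.01, sign checked per
contrast) and 50 for type-I control under the null, at the default 1,300
gene / 200-vs-500 scale — about 3 s per replicate, ~5 minutes for the whole
suite on one CPU. `scripts/acceptance.py` uses one full default run plus 10
recovery and 10 null replicates (~1 minute). These sizes were chosen to
keep each group comparison well powered (the weakest injected effect,
+1 bit on a score with ~2.3-bit spread, exceeds 5 standard errors) while
the suite stays fast enough to run routinely.

## Known limitations

* Exact-coordinate event matching cannot absorb coordinate jitter from
  upstream pipelines; a tolerance-based matcher would be needed for real
  tables with imprecise boundaries.
* The splice-site model is first-order; maximum-entropy models capture
  adjacent-position dependencies and score real sites better.
* The AS fold-change column is treated as an opaque inclusion-ratio input;
  no attempt is made to re-derive it from reads or PSI.
* MXE detection requires exhaustive transcript evidence of exclusivity and
  will under-call MXE in sparsely annotated genes (by design, falling back
  to EC).
* The branchpoint finder reports a single best placement; introns with
  multiple used branchpoints are summarised by one.
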