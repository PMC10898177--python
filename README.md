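# cisplice

Splicing-event classification and cis-regulatory feature analysis for
perturbed transcriptomes.

When cells are treated with splicing-targeting drugs (SF3B1/U2-snRNP
inhibitors, RBM39 degraders, transcriptional-kinase inhibitors), the
transcriptome responds with characteristic alternative-splicing changes:
cassette exons (EC) are included or skipped, introns are retained (IR),
alternative first/last exons (AFE/ALE) and alternative 5'/3' splice sites
are selected. Which exons and introns respond is not random — it is written
in their cis-sequence: the strength of their 3' and 5' splice sites, the
distance of the branchpoint (BP) from the acceptor, the polypyrimidine
tract (PPT), GC content, intron length, and the position of the intron
within the transcription unit. `cisplice` is a toolkit for making those
comparisons reproducible: it derives an event catalogue from a genome
annotation, classifies differential events into patterns, computes the
per-event cis-feature panel, and runs the comparative statistics between
regulated events and reference alternative / constitutive sets. It is aimed
at computational biologists analysing differential-splicing tables produced
by any upstream quantification pipeline.

## The model

**Events.** From a GTF annotation, every exon and intron of every gene is
assigned to exactly one class. An exon present in every transcript is
constitutive; an internal exon present in some but not all transcripts is a
cassette (EC); an intron of one transcript contained in an exon of another
is an annotated retained intron; boundary-sharing exon pairs are
ALT5SS/ALT3SS (resolved by strand); differing non-overlapping terminal
exons are AFE/ALE (in transcription order); two internal exons that never
co-occur are mutually exclusive (MXE). A differential event is matched to
this catalogue by exact coordinates; an event equal to a constitutive
intron is *novel* intron retention (`annotated = False`).

**Splice-site strength** is the log-odds score of a first-order position
weight matrix,

```
S(x) = Σᵢ log₂( pᵢ(xᵢ) / q(xᵢ) )        [bits]
```

over a 9-nt donor window (3 exonic + 6 intronic nt) and a 23-nt acceptor
window (20 intronic + 3 exonic nt), with foreground probabilities `pᵢ`
trained on the annotation's constitutive junctions (pseudocount 1) and
background `q` the genome-wide base frequencies. The branchpoint is the
maximum-scoring placement of a heptamer branch PWM (branch A at position 6)
scanned 18–100 nt upstream of the 3' splice site; the PPT is the longest
contiguous C/T run between the branch A and the acceptor AG, scored T=1.0 /
C=0.5.

**Statistics.** Feature contrasts between groups (e.g. up-regulated
cassettes vs reference cassettes vs constitutive exons) use Welch's
unequal-variance t-test with Satterthwaite degrees of freedom; pattern
enrichment against the annotated catalogue uses the two-sided Fisher exact
test; Benjamini–Hochberg adjustment is applied once across each result set.
Thresholds follow the inclusive rule *fold-change ≥ 2 and p ≤ 0.05* (for
expression: |log₂FC| ≥ 1).

**Validation by parameter recovery.** A synthetic-genome generator emits
FASTA + GTF + differential tables in which regulated event subsets carry
known injected effects — splice sites weakened or strengthened by a
calibrated number of bits, branchpoints moved, GC shifted, introns
shortened and positioned with a Beta-distributed 5'→3' bias — so the entire
pipeline is checked by recovering what was injected.

## Worked example

```python
from cisplice.synthetic import SyntheticSpec, generate
from cisplice.pipeline import analyze_bundle, recovery_table

bundle = generate(SyntheticSpec(), seed=1)      # 1,300-gene genome
result = analyze_bundle(bundle, seed=1)
print(recovery_table(result).round(4).to_string(index=False))
```

```
     feature group_a                 group_b  expected_sign  mean_diff  p_value  sign_correct
   ss3_score   up_EC            ref_cassette             -1    -2.3706      0.0          True
   ss3_score down_EC            ref_cassette              1     0.9089      0.0          True
 bp_distance down_EC            ref_cassette             -1    -9.3630      0.0          True
    gc_event down_EC            ref_cassette             -1    -0.0743      0.0          True
   len_event   up_IR ref_constitutive_intron             -1  -145.6270      0.0          True
rel_position   up_IR ref_constitutive_intron              1     0.2661      0.0          True
```

Each row is one feature contrast between a regulated group and its
reference set. The generator injected a −2-bit 3'ss shift into up-regulated
cassettes, a +1-bit shift plus a 10-nt-closer branchpoint and −0.08 GC into
down-regulated cassettes, and half-length, 3'-biased retained introns; the
pipeline measures −2.37 bits, +0.91 bits, −9.4 nt, −0.074 GC, roughly
half-length introns and a +0.27 shift in mean relative position — every
contrast with the injected sign at vanishing p.

The same analysis is available file-based from the shell:

```bash
cisplice simulate --seed 1 --n-genes 300 --out-dir sim/
cisplice catalog  --gtf sim/annotation.gtf --out-dir out/
cisplice compare  --gtf sim/annotation.gtf --fasta sim/genome.fa \
                  --events sim/events.tsv --expression sim/expression.tsv \
                  --seed 1 --out-dir out/
cisplice report   --dir out/ --out out/report.json
```

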