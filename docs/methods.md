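# Methods

## The measurement being modelled

Both m⁶Am and 5′-UTR m⁶A are pulled down by the m⁶A antibody, so a single
IP cannot separate them. The assay's leverage is chemical: an in-vitro FTO
reaction tuned (by omitting L-ascorbic acid) to remove ≥95% of cap-adjacent
m⁶Am while leaving internal m⁶A essentially untouched. Sequencing the m⁶A-IP
of treated [FTO(+)] and untreated [FTO(−)] aliquots of the same
cap-selected RNA turns the chemistry into a computable contrast:

* a peak that collapses in FTO(+) was m⁶Am;
* a peak that persists was internal m⁶A;
* within an m⁶Am peak, the modified base itself is the transcript's first
  nucleotide, so it is the position where reads *start* rather than merely
  cover — which is what the SRD score measures.

## Peak calling

Windows of 50 nt every 25 nt are tested per contig and strand. The window
statistic is the depth sum divided by the fragment length (150 nt), i.e. an
estimate of the number of fragments in the window, which keeps the
one-sided Poisson test on the scale where its variance assumption is
meaningful; the expectation is the input window count scaled by the library
size ratio, with one pseudo-read. Window p-values are BH-corrected per
strand. A window with fold ≥ `min_fold` (3) and q ≤ `q_cutoff` (0.01) seeds
a peak; the peak extends over chained windows with fold ≥ `boundary_fold`
(1.5). Two-threshold extension is standard peak-caller practice and matters
here because transcript-model callers emit wide peaks: the downstream
high-confidence filter asks for *overlap* between m⁶A-IP and m⁷G-IP peaks,
and narrow fold-3 cores of two different antibodies need not touch even
when their underlying fragment populations do.

Fold enrichment is computed on counts-per-million with a 1-CPM pseudocount
in both numerator and denominator. Unlike a raw "+1 read", this makes folds
(and hence peak intervals, whose extension is fold-gated) exactly invariant
under multiplying any one library's counts together with its size — a
contract the tests pin. The extension is deliberately not significance
gated for the same reason. Reported peak fold/p/q are the best values over
the peak's seed windows, so every emitted peak demonstrably satisfies the
seed cutoffs; the summit is the leftmost position of maximal IP depth.

Counts used for *testing between libraries* (classification, condition
comparisons, site criterion 4) are read 5′-end counts summed over
intervals — genuine read counts, as Fisher margins require — while the
window scan uses depth sums as its enrichment statistic. mpileup ingestion
takes depth from column 4 and start counts from `^` markers; strand
splitting is assumed done upstream (the workflow maps strand-specifically
and splits BAMs before pileup).

## Classification

Each high-confidence 5′-region peak is tested FTO(−) vs FTO(+) with a
two-sided Fisher exact test on [reads in peak vs library remainder] ×
[FTO(−) vs FTO(+)], BH-corrected across all peaks of the run. The original
workflow demanded joint exomePeak and DESeq2 evidence; with no replicate
structure guaranteed, a single exact count test is the deterministic,
dependency-free replacement, and the ratio/q cutoffs are exposed in
`ClassifyParams`. The verdict is M6AM when RPM ratio > 2 and q < 0.01;
UTR5_M6A when the signal did not decrease (ratio ≤ 1) or changed without
significance at ratio ≤ 2; AMBIGUOUS otherwise (significant 1–2-fold drops,
and large but non-significant drops). Forcing the ambiguous middle ground
into either class would fabricate certainty the counts do not support.

## SRD site calling

m1 is a within-library ratio, so it needs no normalisation; the depths in
m2 are RPM-normalised by default because raw depths would make m2 depend on
the FTO(+)/FTO(−) sequencing-depth ratio (`normalized=False` reproduces the
raw behaviour). FTO(+) *coverage*, not start rate, enters m2: the FTO(+)
start signal at a demethylated position is near background. The five
criteria are evaluated vectorised over the peak; the "top 3" rank of
criterion 5 is computed over all positions of the peak with defined SRD
(FTO(−) depth > 0), independent of the other criteria, with ties at rank 3
all included — a stricter, evaluation-order-independent reading than
ranking only pre-filtered positions, and per *peak* rather than per gene
(a per-gene mode would couple unrelated peaks of multi-peak genes). Motif
context is read sense-strand 5′→3′: BCA iff base(−1)=C and base(−2)∈{C,U,G};
fewer than two upstream bases ⇒ undefined.

## Condition comparisons

Peaks of the two conditions are harmonised by merging same-strand
≥1-bp-overlapping intervals, so a peak absent in one condition is still
testable over the merged interval. Intensities are FTO(−) m⁶A-IP RPM for
both peak classes. Stress responsiveness uses fold > 2 with BH q < 0.01
(both directions, strict inequalities); PCIF1 dependence uses WT/KO
ratio > 2 with raw P < 0.05, matching its looser published definition. The
"difference > 2" in the stress definition is implemented as fold change —
the volcano-plot semantics of the source analysis — not absolute
difference.

## The synthetic benchmark

`SimConfig` defaults *are* the study conditions: 500 transcripts (mean
3.2 kb), 70% carrying m⁶Am at an A-starting TSS, 20% carrying one internal
5′-UTR m⁶A in a GGACH context, 100× mean input coverage, fragments
150 ± 30 nt, m⁶A-antibody enrichment 10× per methylated fragment, FTO
demethylation efficiency 0.95 for m⁶Am and 0 for m⁶A, 66% BCA context.
Libraries are serial: the m⁷G-IP weights cap-retaining fragments 3×, and
the m⁶A-IP multiplies a further 10× on methylated fragments, so the FTO
contrast rides on top of cap selection as in the assay. Counts are Poisson;
fragment 5′ ends are uniform within transcripts except cap fragments,
whose 5′ end is the TSS — reproducing the sudden 5′ drop-off the SRD score
exploits without a read-level simulator.

Three second-order features are modelled because the site criteria are
degenerate without them:

* **minor alternative TSSs** (5% of caps, 10–60 nt upstream, never
  methylated): real promoters are heterogeneous, and this unmethylated
  halo is what makes the FTO(−) start rate at the true TSS exceed the
  m⁷G-IP's (criterion 3) — with perfectly homogeneous TSSs both rates are
  exactly 1 and the comparison is a coin flip on sampling noise;
* **downstream-only cap-end jitter** (2%, +1/+2 nt): 5′-end wobble from
  nibbling/end repair exists, but a capped RNA has no nucleotides upstream
  of its first transcribed base, so the jitter is one-sided;
* **uniform genomic background** (5% of fragments) so no position has
  identically zero competing coverage.

Planted m⁶A sites sit 150–190 nt into the 5′-UTR: far enough from the TSS
that cap-fragment coverage does not dilute their own enrichment below the
fold-3 cutoff, close enough that their peaks overlap the m⁷G-IP cap peak —
the geometry real 5′-UTR m⁶A peaks have, given that human 5′-UTRs are
short. The m⁷G-IP scan in the bundled pipeline runs with `min_fold=1.2`:
its expected per-region fold (cap carryover over an input that also
contains the cap fragments) is only ≈2.5, so the m⁶A-IP's fold-3 rule
would be miscalibrated for it.

What the generator does **not** model: sequencing error, mappability and
alignment artifacts, isoform mixtures sharing exons, transcripts carrying
both marks (`frac_m6am + frac_m6a ≤ 1` partitions them), overdispersion
beyond Poisson, and replicate structure. Passing tests therefore
demonstrate the statistical machinery and its calibration under the
modelled causal structure, not robustness to real-library artifacts.

## Numerical and interface choices

Coordinates are 0-based half-open everywhere internally and in BED output;
the mpileup reader converts from 1-based at the boundary; a minus-strand
TSS is the interval end − 1. Tracks are dense per-contig arrays (desk-scale
contigs are ≤ ~120 kb; no chunking is implemented). Library sizes default
to total start counts when not supplied. Summit ties break leftmost; output
ordering is (contig, start, strand); BED floats are written at full
precision so write→read round trips are exact identities. Peak–gene
assignment uses the 5′-UTR extended 100 nt upstream of the annotated TSS
(annotated TSSs and true cap sites often disagree); the margin is
configurable and peaks outside any 5′ region are flagged, not silently
dropped.

Problem sizes in the test suite (60–150 transcripts for unit-level
end-to-end checks, the full 500-transcript benchmark over ten seeds for the
acceptance quantities) were chosen so the whole suite runs in well under a
minute on one CPU while keeping every planted-effect margin several
standard errors wide.

## Known limitations

The Fisher test treats reads as exchangeable between conditions (no
biological replicate variance); the AMBIGUOUS class absorbs what replicated
designs would resolve. exomePeak/MACS2 numerical parity is not a goal. The
caller is transcriptome-oriented: it scans provided coverage, it does not
discover unannotated transcription. Internal (non-cap) m⁶Am is outside the
assay's reach and therefore outside the package's.
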