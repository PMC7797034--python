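# Methods

`mirclip` analyses probe-capture (miR-CLIP-style) experiments: a
pre-miRNA probe carrying a photo-crosslinker and an affinity handle is
processed to a mature miRNA in cells, crosslinked to its bound mRNAs, and
the crosslinked transcripts are enriched by AGO2 immunoprecipitation plus
streptavidin pulldown and sequenced. The package covers the downstream
computation: ranking captured transcripts into a targetome, calling
seed-match and G-bulge target sites under shifted 5' isomiR registers,
motif-enrichment and transfection-response statistics, and isomiR
quantification from small-RNA reads. A synthetic-data generator produces
complete, ground-truthed inputs so every stage is testable without
sequencing data.

## Registers and site classes

A miRNA is a `MirnaRegister`: guide sequence (5'→3', ACGU, length 16–30)
plus an integer register offset counting extra 5' nucleotides relative to a
declared base register. Two isoforms of one hairpin arm satisfy
extended g(k+1) = base g(k). Canonical site classes are built from the
seed: 8mer (pairs g2–g8, A opposite g1), 7mer-m8 (g2–g8), 7mer-A1 (g2–g7 +
opposite-A), 6mer (g2–g7), offset 6mer (g3–g8). Target-side motifs are the
reverse complement of the paired span written 5'→3' on the target, so the
nucleotide opposite g1 sits at the motif's 3' end. The A1 rule requires a
genomic A opposite g1 and does not require g1 pairing — for guides
beginning with U (the common case here) the A also happens to pair.

G-bulge classes model the non-canonical site in which a target guanosine
bulges out between the nucleotides opposite g5 and g6: the 7mer-m8 motif
with one G inserted at motif index 3 (between t6 and t5), optionally plus
the terminal A (G-bulge 8mer). The scan criterion is full pairing of g2–g8
plus the inserted G; the transient g2–g6 nucleation proposed mechanistically
for such sites is not a sequence filter. Under a +1-extended register the
same physical bulge sits between the nucleotides opposite g6 and g7
(`map_bulge_span`), which is the structural basis for isoform-selective
G-bulge targeting.

`classify_site` returns the single strongest class at an anchor
(8mer ⊃ 7mer-m8 ⊃ offset-6mer and 7mer-A1 ⊃ 6mer are nested, so weaker
co-calls at the same anchor are suppressed; this avoids double counting in
enrichment statistics). `cross_register_class` re-anchors a site's window
one position and re-classifies under the other register rather than using a
lookup table; supplying flanking nucleotides is required because flanks can
genuinely upgrade a class (a base-register 8mer is an extended-register
8mer exactly when an A sits opposite extended g1, i.e. in the 3' flank).

One subtlety discovered while testing: for guides with g6 = C (such as the
default miR-124-like guide) the G-bulge 8mer motif intrinsically contains a
6mer for the +1-extended register, because the bulged G equals the
complement of g6. With the most conservative canonical-exclusion floor
(6mer) such sites therefore self-exclude from the G-bulge candidate funnel;
the 7mer floor does not have this property.

## Scanning

Transcripts are sense-strand sequences in 0-based half-open transcript
coordinates; 3'UTRs arrive as BED with the transcript ID in the chrom
column (no genome coordinates exist anywhere in the analysis). The scanner
reports all (possibly overlapping) occurrences of all supplied patterns,
strongest class per (start, miRNA) anchor, sorted deterministically. Sites
straddling the UTR boundary are assigned by their start position. N or any
other ambiguity code is rejected at parse time, so it can never match.

## Enrichment model and targetome

Samples are `input`, `ago_ip` or `mir_clip`. Counts are normalized with
median-of-ratios size factors (geometric-mean reference over transcripts
detected in every sample; total-count fallback when fewer than 50 such
transcripts), scaled to geometric mean 1. The per-transcript test is an
exact conditional test: normalized counts are summed within each group and
the CLIP-group sum, conditioned on the two-group total s, is compared to
its null distribution — the normalized product of the two group-sum NB
probability masses with a common dispersion φ (group sums of n replicates
have dispersion φ/n), which reduces to Binomial(s, n_b/n) at φ = 0. The
two-sided p sums probabilities of all outcomes no more likely than the
observed split. φ is a single common value (2–4 replicates per condition
make per-transcript estimation unstable), estimated by the method of
moments φ̂ = mean over transcripts of max(0, (v−m)/m²) with v the pooled
within-group variance; a trim parameter exists but defaults to 0 because
symmetric trimming of these right-skewed estimates biases φ̂ low and makes
the test anticonservative.

Fold changes are log2((CPM_b + 0.5)/(CPM_a + 0.5)) on counts-per-million of
the mean normalized library; CPM units make log_fc exactly invariant to
rescaling any single sample. The targetome keeps transcripts with positive
logFC, ranked by raw p (ties by |logFC| then ID), truncated to n_top
(default 1000); BH q-values are computed over all tested transcripts before
filtering and are reported, not used for ranking.

## Motif enrichment and response shift

Expected motif occurrences come from either B = 100 per-sequence
mononucleotide-preserving shuffles (default; composition held exactly,
seeded) or a cohort of background sequences scaled by total scannable
positions — the right null is a modelling choice, so both are exposed.
Significance is a one-sided Poisson upper tail at the expected count; BH
within the motif family is reported descriptively.

Subset response shifts are summarized by the median logFC, the Δmedian vs
the complement, and a two-sided Wilcoxon rank-sum p. The rank-sum test is
in-repo: the exact permutation distribution is computed by a subset-sum
dynamic program over doubled midranks (equivalent to full enumeration,
ties included) whenever both sides have ≤ 12 observations, and a
tie-corrected normal approximation (no continuity correction) otherwise.
ECDF points are exported for plotting. A 2^−ΔΔCp helper converts qPCR
crossing points (target and housekeeping gene, treated and calibrator) to
fold changes.

## G-bulge candidate funnel

Two probes' ranked targetomes are intersected at a chosen depth; shared
transcripts are kept when they carry ≥ 1 base-register G-bulge site and
excluded when they carry any canonical site (either register) at or above
the exclusion floor within the chosen scope. Defaults are the most
conservative reading — 6mer floor, whole-transcript scope — with
`sevenmer`/`utr3` flags, since the funnel's purpose is isolating
G-bulge-only regulation. The report is fully auditable: every exclusion
lists its offending matches, and shared = final + excluded_canonical +
excluded_no_gbulge always holds. Intersection happens before G-bulge
filtering.

## IsomiR quantification

A small-RNA read is assigned to a 5' start when it is an exact, unique
substring of the hairpin, starts inside the mature-arm window and has
length 18–26 nt. Reads matching at multiple positions are counted as
ambiguous, everything else as unassigned; assigned + unassigned + ambiguous
= total. Exactness is deliberate: the quantity of interest is a single
nucleotide of 5' start resolution, and the generator produces exact reads;
no mismatch or 3'-trimming model is attempted. The abundance ratio between
two 5' starts is computed per library, pooled by geometric mean, and tested
with a two-tailed paired t-test on log10 counts (consistent with the
log-scale pooling); zero counts get a 0.5 pseudocount with a warning.

## Synthetic data

The generator emulates the capture experiment under these default
conditions (chosen to match the analysis scenarios the pipeline is
validated on): transcripts 1–3 kb, GC 0.45, 3'UTR = final 40%; capture
enrichment factor 3 for site-bearing transcripts; 3 input + 3 capture
replicates, NB dispersion 0.1, lognormal baselines (median 150 counts);
transfection response effects per class (8mer −0.35, 7mer-m8 −0.25,
7mer-A1 −0.15, 6mer −0.08, offset 6mer −0.05, G-bulge 0 — G-bulge sites
leave mRNA levels untouched, their regulation being protein-level), noise
sd 0.4; isomiR mixing ratio 3.4 (extended:base) over 100k reads in 4
libraries, read lengths 20–23.

Backgrounds are i.i.d.-composition sequences iteratively scrubbed of *all*
site classes of the configured register pair, then planted motifs are
written at recorded positions with flanks re-drawn (bounded retries) until
an internal naive matcher confirms that (a) each planted site classifies
exactly as planned and (b) every match on the transcript lies inside a
planted window. The recorded truth therefore lists every match a scanner
must find — including the nested weaker-class matches a planted motif
implies at shifted anchors (a 7mer-m8 always contains a 6mer at start+1,
and a base-register site generally contains shifted-register matches) —
making recall and precision exactly 1 testable. Everything is
deterministic under the seed, byte-for-byte.

What the generator does not emulate: real 3'UTR composition and repeat
structure, expression-correlated site occurrence, crosslinking sequence
bias, partial/mismatched sites, 3' isomiRs, sequencing error and adapters.
Passing tests demonstrate correctness of the computations under the stated
noise models, not performance on real libraries.

## Numerical and design notes

- p-values are clipped into (0, 1]; exact-test tie comparison uses a 1e-10
  log-probability tolerance.
- Targetome ordering is fully deterministic (p, |logFC|, ID; mergesort).
- The generator rejects infeasible plans (motif longer than its region) and
  raises after bounded retries rather than silently degrading.
- The CLI (`simulate`, `targetome`, `sites`, `gbulge`, `isomir`,
  `response`) is a thin layer over the library; every run writes a
  `manifest.json` without timestamps, so identical invocations produce
  byte-identical output trees.
- Problem sizes in the test-suite simulations (5000 transcripts for
  calibration/recovery, 300 for motif enrichment, 100k reads for isomiR
  recovery) are the package's validation conditions; stochastic recovery
  checks average a small number of replicate simulations because a single
  draw sits within sampling noise of the acceptance bound.

## Known limitations

- No thermodynamic duplex scoring, 3'-supplementary pairing, or structural
  feasibility modelling of the bulge; the register mapping is annotation.
- The enrichment stage targets calibration and recovery, not numerical
  equality with any external differential-expression tool.
- Gene-level collapsing of the targetome is not implemented (transcript
  level only).
- Exact rank-sum is limited to ≤ 12 per side; beyond that the normal
  approximation is used.
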