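# mirclip

Analysis toolkit for probe-capture miRNA targetome experiments
(miR-CLIP-style), with first-class support for 5' isomiR seed registers and
non-canonical G-bulge target sites.

A pre-miRNA probe bearing a psoralen photo-crosslinker and a biotin handle
is processed into a mature miRNA in cells, crosslinked to its bound mRNAs,
and the crosslinked transcripts are enriched (AGO2 IP + streptavidin) and
sequenced. This package implements the computation downstream of the count
matrices:

- **Targetome ranking** — median-of-ratios normalization and an exact
  conditional negative-binomial test per transcript; the targetome is the
  top-N transcripts with positive log2 fold change (capture vs input),
  ranked by p-value.
- **Site scanning under isomiR registers** — canonical seed classes
  (8mer, 7mer-m8, 7mer-A1, 6mer, offset 6mer) and G-bulge sites (a target
  guanosine bulged between the nucleotides opposite seed positions g5–g6),
  for a base register and its 5'-shifted isoform, on whole transcripts or
  annotated 3'UTRs. Because extended g(k+1) = base g(k), one physical site
  changes class between isoforms; `cross_register_class` computes that
  re-classification and the bulge re-maps to between g6–g7.
- **Motif enrichment** — observed vs expected k-mer occurrences under a
  seeded mononucleotide-shuffle or cohort background, Poisson tail p.
- **Response statistics** — median logFC shift of gene subsets vs their
  complement with an in-repo Wilcoxon rank-sum test (exact permutation
  distribution up to 12 per side), ECDF export, and a 2^−ΔΔCp qPCR helper.
- **G-bulge candidate funnel** — intersect two probes' targetomes, keep
  transcripts with G-bulge sites, exclude any carrying canonical sites for
  either isoform, with a full audit trail.
- **IsomiR quantification** — exact-substring read counting by 5' start on
  the pre-miRNA hairpin, abundance ratios pooled by geometric mean, paired
  t-test on log10 counts.
- **Synthetic data** — a deterministic generator that plants sites,
  enrichment factors, response effects and isomiR mixtures with a recorded
  ground truth, so the whole pipeline is testable end to end.

## Worked example

Target-side patterns for a register (miR-132, guide starting `UAACAGUC`):

```python
from mirclip import build_register, canonical_patterns, gbulge_patterns

reg = build_register("miR-132", "UAACAGUCUACAGCCAUGGUCG")
for p in canonical_patterns(reg) + gbulge_patterns(reg):
    print(f"{p.site_class.value:>12}  {p.motif:<10} pairs g{p.paired_guide_span[0]}-g{p.paired_guide_span[1]}")
```

```
        8mer  GACUGUUA   pairs g2-g8
     7mer-m8  GACUGUU    pairs g2-g8
     7mer-A1  ACUGUUA    pairs g2-g7
        6mer  ACUGUU     pairs g2-g7
 offset-6mer  GACUGU     pairs g3-g8
  gbulge-7m8  GACGUGUU   pairs g2-g8
 gbulge-8mer  GACGUGUUA  pairs g2-g8
```

The motif is the reverse complement of the paired guide span written 5'→3'
on the target; A1 classes append the adenosine opposite g1, and the G-bulge
motifs carry one extra G between the nucleotides opposite g6 and g5.

End to end from a simulated experiment (300 transcripts, a quarter carrying
one planted 7mer-m8, 3-fold capture enrichment, NB noise):

```sh
mirclip simulate  --out sim --seed 1 --n-transcripts 300 --n-reads 20000
mirclip targetome --counts sim/counts_probe1.tsv --samples sim/samples_probe1.tsv \
                  --out tgt --n-top 100
head -4 tgt/targetome.tsv
```

```
transcript_id   logFC                p                       q                       rank
TX051           2.165519203187351    5.840569291226676e-08   9.722470512995847e-06   1
TX020           2.1723079114452286   6.481647008663898e-08   9.722470512995847e-06   2
TX007           2.0969175211705813   1.4825240850445613e-07  1.4825240850445614e-05  3
```

The top-ranked transcripts are planted site carriers: logFC ≈ 2^2.17 ≈ 4.5
observed against the 3-fold planted enrichment plus the 0.5-CPM pseudocount
and sampling noise, with q-values from BH over all 300 tested transcripts.

IsomiR abundance from the simulated small-RNA libraries (two 5' starts one
nucleotide apart on the hairpin, true mixing ratio 3.4):

```sh
mirclip isomir --reads sim/reads_lib1.fa --reads sim/reads_lib2.fa \
               --reads sim/reads_lib3.fa --reads sim/reads_lib4.fa \
               --hairpin sim/hairpin.fa --window 25:31 --offset-a 28 --offset-b 27 \
               --out iso
```

```
isomir: pooled ratio 3.350 over 4 libraries
```

`iso/isomir_summary.json` records per-library ratios (3.29–3.37), the
pooled geometric-mean ratio 3.350, and the paired t-test on log10 counts
(p = 2.3e-07) — recovering the configured 3.4 within sampling error.

Further subcommands: `mirclip sites` (site-match and count tables),
`mirclip gbulge` (two-probe overlap + G-bulge candidate funnel with JSON
audit), `mirclip response` (subset logFC-shift statistics + ECDF export).
See `docs/methods.md` for the models, defaults and their rationale.

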