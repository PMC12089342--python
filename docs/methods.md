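# Methods

## The measurement model

Elongating ribosomes protect ~20–34 nt of mRNA from nuclease digestion.
After size selection and alignment, the 5′ end of a ribosome-protected
fragment (RPF) sits a characteristic distance upstream of the codon being
decoded: ~15 nt to the A-site codon and ~12 nt to the P-site codon. A
shortage of a charged tRNA lengthens the dwell time of ribosomes whose A
site holds the cognate codon, which raises the frequency of RPFs whose
5′-end-plus-15-nt triplet equals that codon. `stallscan` quantifies this at
three levels: per codon (subsequence shift), per amino acid (mixed model),
and per position around codon occurrences (density profiles), with an
off-frame background supplying the significance null.

## Footprint filtering and assignment (`rpf_io`)

Reads enter codon-level analysis only when

- aligned length ≥ 27 nt (the "> 26 nt" rule read as a strict inequality);
- the 5′ end projects into `[CDS_start − 15, CDS_end − 27]` of at least one
  transcript on the matching strand — the 15-nt upstream allowance reflects
  footprints of initiating ribosomes whose protection extends past the
  start codon;
- all compatible transcripts belong to one gene and agree on the reading
  frame (frame = CDS-relative 5′ position mod 3; negative overhang
  positions are reduced into {0,1,2} so offset arithmetic stays in frame).

Everything else is rejected into a `FilterReport` whose categories always
sum to the input count. Unmapped records count as outside-CDS;
secondary/supplementary alignments (multi-mappers) as gene-ambiguous, since
unambiguous gene assignment is a hard requirement. Soft clips are excluded
from the 5′ end; spliced reads are projected through the CDS intervals and
rejected when the 5′ end lands in an intron.

The minimum-length filter is applied uniformly to all analyses (subsequence,
density, out-of-frame) and is exposed as a parameter.

## Subsequence shift (`subsequence_shift`)

For sample *s*, gene *g* and codon *c*, let `n_s(g,c)` be the number of
retained RPFs whose in-frame triplet at the chosen offset (15 nt = A site by
default; configurable) equals *c*; out-of-frame reads contribute nothing and
stop-codon triplets are dropped. Within-gene frequencies
`f_s(g,c) = n_s(g,c) / Σ_c n_s(g,c)` remove expression differences. Genes
with ≥ `min_gene_count` (default 100) total counts in **both** samples are
averaged unweighted (one gene, one vote; a count-weighted average is
available behind a flag), and

```
shift(c) = (f̄_cond(c) − f̄_ctrl(c)) / f̄_ctrl(c).
```

The same gene set serves all codons (the threshold is on gene totals, not
per-codon counts). Codons unseen in both samples are omitted; codons with a
zero control mean are reported flagged rather than silently dropped.
Because the statistic depends only on within-gene frequencies it is exactly
invariant to uniform count scaling, and swapping the samples maps
`s → 1/(1+s) − 1`.

Offset indexing is 0-based: "15 nt from the 5′ end" means the triplet
occupying read positions 15–17. This is the convention consistent with the
15-nt overhang arithmetic; the offset is configurable because other
conventions exist. A fixed offset is used for all read lengths;
length-dependent offsets can be emulated by filtering on length and
offsetting per subset.

### Amino-acid-level inference

Replicate-level codon shifts are stacked and fitted by REML with
`statsmodels` MixedLM:

```
shift ~ 0 + amino_acid,  random intercept per codon
```

Each amino acid is contrasted against the grand mean of the amino-acid
effects (Wald *t*); p-values are Benjamini–Hochberg adjusted across the
amino acids tested. Replicates enter as independent rows (no replicate
random effect — only codon-level correlation is modelled). A singular fit
(codon variance ≤ 1e−4 × residual variance, the lme4-style relative
tolerance) falls back to the fixed-effects-only linear model with a logged
warning; an all-constant response short-circuits to t = 0, p = 1. The
genetic code is the standard nuclear code; selenocysteine recoding is
ignored.

## Density profiles (`density_profiles`)

Every in-frame occurrence of the query codon defines a 61-nt codon-region:
30 nt upstream, the codon's first nucleotide, 30 nt downstream (the
anchoring is configurable in principle; the window width is fixed at 61).
Occurrences whose window would cross a CDS end are excluded. Regions from
different transcripts with identical genomic coordinates collapse to one;
overlapping-but-distinct regions are all kept.

Per region, 5′-end counts are normalised by `total/61` so each region has
mean density exactly 1, then smoothed with a width-3, height-1/3 rectangular
kernel. **Boundary rule:** the window edges replicate their own value for
the missing neighbour. This keeps the kernel exactly mean-preserving, so the
"average density 1" contract survives smoothing; the cost is that an edge
position with 3-nt-periodic signal appears visually doubled. Smoothing is
applied per region before cross-region averaging (the two orders differ
only through boundary handling).

The joint filter keeps regions with ≥ `min_region_count` (default 50) total
counts in every sample. If fewer than `min_windows_common` (default 1000)
regions survive for a codon that has more candidates available, the
threshold is lowered 50 → 40 → 30 → 20 → 10 until enough regions survive or
the floor is reached; the schedule walked is recorded in the result and the
run manifest. The density shift is the elementwise difference of the
samples' mean smoothed profiles; a stalled codon peaks at window position
−15 (the A-site 5′-end placement), spread over ±1 position by the kernel.

## Out-of-frame Z-test (`outofframe`)

Off-frame triplets — read at offsets 14 and 16 while selecting reads by
frame at offset 15 — are not decoded by the ribosome, so their shifts
estimate the technical/compositional null. All 64 triplets per side enter,
except those that physically overlap the target codon by two bases and
would therefore carry its true signal: for target `b0 b1 b2`, pattern
`N b0 b1` on the −1 side and `b1 b2 N` on the +1 side (GCA → NGC and CAN).
The literal "11th/13th position" presentation indexing is resolved by this
overlap rule, which reproduces the GCA example exactly.

The observed in-frame shift is scored as
`z = (observed − mean_bg) / sd_bg` (sample SD, n−1 denominator — the
background holds at most ~120 values) with a two-tailed normal p-value.
Anderson–Darling and Shapiro–Wilk statistics and Q–Q coordinates are
attached as diagnostics only; a Shapiro–Wilk p < 0.05 sets a flag but never
suppresses the result. A zero-variance background (condition ≡ control)
returns an explicitly degenerate result. Fewer than 8 surviving background
values aborts with a diagnostic.

Calibration note: because `sd_bg` pools triplets of heterogeneous frequency
(and hence heterogeneous sampling variance), the test is mildly
conservative under the null — measured false-positive rate ≈ 0.03 at
α = 0.05, p-value KS distance from uniform ≈ 0.09 over 500 null
repetitions at the sizes below.

## The simulator (`synthetic_ribo`) and what it does not model

Per read: transcript ∝ expression weight (log-normal, σ = 1); A-site codon
within the CDS ∝ dwell multiplier (uniform base dwell, stop codons never,
start codon never); 5′ end = A-site − 15 nt, displaced ±1 nt with the
configured jitter probability (split evenly); length from a triangular
distribution over 20–34 nt with mode 30 (the experimental size-selection
window; the mode is a plausible placeholder since empirical length
distributions vary by protocol, and it is configurable). A-site candidates
keep `a_site_offset` nt clear of the CDS start and
`max_read_length − a_site_offset` nt clear of the end (plus 1 nt when
jitter is on), so no read can overhang — which makes the per-codon A-site
probability exactly computable by summing position weights
(`analytic_asite_distribution`), the oracle the tests converge to. With a
single stalled codon at multiplier *m* and sequence frequency *f*, the
occupancy is `m·f / (1 + (m−1)·f)` per transcript.

Deliberately not modelled: sequencing errors, adapter artefacts, UMI
collisions, rRNA contamination, ligation-sequence bias beyond an optional
per-codon capture multiplier, spliced/genome-coordinate alignment, UTRs
(transcripts are CDS-only, so the 5′-overhang code path is exercised by
hand-built fixtures rather than the simulator). Consequently, passing tests
demonstrate correctness of the statistics under the stated sampling model —
not robustness to library-preparation artefacts in real data, where
signal-to-noise is the binding constraint.

## Validation experiment sizes

Chosen to make every experiment reproducible in minutes on one core:
ranking/mixed-model recovery and the out-of-frame detection rate use a
200-gene transcriptome (300–1800 nt) at 10⁶ reads per library, 3 replicate
pairs and 20 repeats; null calibration uses 100 genes (300–900 nt) at
5×10⁴ reads × 500 repetitions for the Z-test and 25 experiments × 2
replicate pairs at 10⁵ reads for the amino-acid false-positive rate. A 3×
dwell on the four alanine codons yields in-frame shifts ≈ 1.6 and
out-of-frame z ≈ 12–14 at these sizes.

## Known limitations

- Isoform mixing: region profiles match reads to regions by transcript;
  reads are assigned one representative transcript per gene (longest CDS),
  so minor-isoform-specific regions of multi-isoform genes are
  approximated. Synthetic data are single-isoform.
- The out-of-frame background is slightly conservative (above); strongly
  stalled codons sharing two bases with other stalled codons inflate the
  +1-side background when only the target's own overlap patterns are
  excluded — with a 4-codon alanine stall the z-scores remain ≫ 3.
- The mixed model treats codon shifts as homoskedastic; rare codons have
  noisier shifts, which the codon random effect absorbs only partially.
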