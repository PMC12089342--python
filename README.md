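# stallscan

Codon-resolved detection of ribosome stalling from ribosome-profiling
(Ribo-seq) data.

When a cell runs short of an amino acid, the cognate tRNAs lose their charge
and ribosomes dwell longer with that amino acid's codons in the A site.
`stallscan` turns that dwell signal into statistics: it compares the codon
occupancy of ribosome-protected fragments (RPFs) between a condition and a
control library and reports which codons — and which amino acids — show
elevated ribosome residence. It is aimed at researchers analysing aligned
Ribo-seq libraries (bulk or cell-type-resolved) who want a tested,
reproducible implementation of the subsequence-shift ("diricore"-style)
analysis together with a ground-truth simulator for validating it.

## What it computes

For each retained RPF (length > 26 nt, unambiguous gene and reading frame,
5′ end inside the CDS allowing a 15-nt 5′ overhang), the triplet 15 nt from
the 5′ end is the A-site codon (12 nt: P site). Counts are normalised within
each gene and averaged across genes with ≥ 100 counts in both samples. The
per-codon statistic is the **subsequence shift**

```
shift(c) = ( f̄_cond(c) − f̄_ctrl(c) ) / f̄_ctrl(c)
```

where `f̄_s(c)` is the across-gene mean of within-gene codon frequencies in
sample *s*. Three layers of inference sit on top:

- **Amino-acid test** — replicate-level codon shifts enter a linear mixed
  model, `shift ~ amino_acid + (1 | codon)` (REML), each amino acid tested
  against the grand mean (Wald *t*), Benjamini–Hochberg corrected.
- **Out-of-frame Z-test** — the null distribution for a codon's shift is
  built from the shifts of triplets read ±1 nt off frame at the same
  position, excluding triplets that overlap the target by two bases
  (for GCA: N**GC** at −1 and **CA**N at +1); the observed shift is scored
  with a two-tailed Z-test, with Anderson–Darling / Shapiro–Wilk / Q–Q
  normality diagnostics attached.
- **Density profiles** — 61-nt windows centred on every in-frame occurrence
  of a codon; per-region 5′-end densities are normalised to mean 1, smoothed
  with a width-3 rectangular kernel, averaged, and differenced between
  samples (the **density shift**), which peaks 15 nt upstream of a stalled
  codon.

The `synthetic_ribo` module generates transcriptomes and footprint libraries
with known stalling (per-codon dwell multipliers, 20–34 nt reads, configurable
±1 nt offset jitter), so every statistic can be validated against ground
truth and an exact closed-form occupancy law.

## Worked example

```python
import stallscan as ss

# transcriptome of 200 genes; condition stalls the four alanine codons 3x
tx = ss.generate_transcriptome(n_genes=200, length_range=(300, 1800),
                               gc_fraction=0.5, seed=1)
seqs = {t.gene_id: t.cds_sequence for t in tx}

def library(profile, seed):
    reads = ss.simulate_footprints(tx, ss.StallingProfile(profile),
                                   ss.SimulationConfig(n_reads=1_000_000, seed=seed))
    return ss.to_aligned_rpfs(reads)

ala = {c: 3.0 for c in ("GCA", "GCC", "GCG", "GCT")}
cond, ctrl = library(ala, seed=10), library({}, seed=20)

tab_c = ss.count_codons_at_offset(cond, seqs, offset=15)
tab_k = ss.count_codons_at_offset(ctrl, seqs, offset=15)
shifts = ss.compute_shifts(tab_c, tab_k, min_gene_count=100)
print(shifts.nlargest(4, "shift")[["codon", "amino_acid", "shift"]])

for r in ss.oof_tests(cond, ctrl, seqs, ["GCA", "GCC", "GCG", "GCT"]):
    print(r.target_codon, f"z={r.z:.2f}", f"p={r.p_two_tailed:.3g}")
```

prints

```
   codon amino_acid     shift
36   GCA          A  1.695967
38   GCG          A  1.652144
39   GCT          A  1.611055
37   GCC          A  1.576483
GCA z=13.65 p=2.12e-42
GCC z=12.39 p=2.88e-35
GCG z=12.82 p=1.3e-37
GCT z=12.80 p=1.73e-37
```

The four largest shifts are exactly the four alanine codons (a ~1.6-fold
relative occupancy increase, consistent with a 3× dwell after gene
normalisation), and each is far outside its out-of-frame background
(two-tailed p ≪ 0.01).

A full pipeline run (simulate → QC → shift → density → out-of-frame, with a
checksummed manifest) is driven by a YAML config:

```
stallscan run --config run.yaml
```

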