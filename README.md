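# ithpipe

Multi-region intra-tumor heterogeneity (ITH) analysis for solid tumors
sequenced region by region — for instance cohorts in which each
spatially distinct tumor region is cultured as a high-purity
patient-derived primary cancer cell line (PDPC) before whole-exome and
RNA sequencing.  Given per-region somatic variant tables, copy-number
segments and expression counts, `ithpipe` quantifies how much of a
tumor's mutational, copy-number and transcriptional landscape is shared
by every region and how much is confined to subsets of regions.

The package is aimed at cancer-genomics analysts who already have
upstream calls (aligner, somatic caller, annotator, CNV segmenter,
read counter) and need the downstream heterogeneity analysis to be
reproducible, scriptable and testable.  A fully deterministic
synthetic-data module generates cohorts with known ground truth for
every stage, so each component can be validated end to end without
access to patient data.

## What it computes

**Somatic hard filter.**  Annotated SNV/INDEL calls are kept when, in
order: strand bias < 0.9 (majority-strand fraction of alt reads);
depth ≥ 20 and alt reads ≥ 8; VAF ≥ 0.1; not a common dbSNP variant
(AF ≥ 1%); not a common CONVERGE SNP; not a 1000 Genomes gold-standard
INDEL; AF ≤ 0.015 in 1000 Genomes, ESP6500 and ExAC; exonic or
splicing.  Every rejection is attributed to its first failing
criterion.

**Phylogeny and ITH score.**  Per patient, passing mutations (silent
and non-silent) form a binary presence/absence matrix over region-
samples.  Mutations present in all regions are *trunk*, in >1 but not
all *shared*, in exactly one *private*.  An unrooted maximum-parsimony
tree over the regions plus an all-absent germline outgroup is found
either exactly (exhaustive enumeration, ≤ 8 regions) or by the
parsimony ratchet (iterated SPR hill climbing under periodically
reweighted characters), scored with the Fitch algorithm on binary
characters.  Branch lengths are mutation counts placed by a minimal
Fitch backtrace.  Two ITH definitions are reported side by side:

  - `methods`: 100 · n_trunk / n_non-trunk,
  - `nontrunk_fraction`: 100 · n_non-trunk / n_total.

**Drivers.**  A variant in a user-supplied curated gene list is a
putative driver if it is truncating (nonsense, splicing, frameshift)
or a missense call rated deleterious by SIFT or PolyPhen.

**Mutational signatures.**  Six-class and 96-trinucleotide-context
spectra for trunk versus non-trunk SNVs; a chi-square proportions test
(with continuity correction in the 2×2 case) between them; and greedy
non-negative-least-squares deconvolution of each spectrum against a
reference signature matrix (exposures below 0.06 discarded).  The
bundled 30-signature reference is a synthetic stand-in
(`signatures_synthetic_30x96.tsv`) with the field's qualitative
structure; substitute your own matrix via `--reference`.

**CNV heterogeneity.**  X/Y segments excluded; per cytoband and
region-sample the length-weighted mean log2 ratio is called gain above
+0.3 and loss below −0.3; per patient a band is ubiquitous
(same non-neutral call in every region), heterogeneous, or absent.

**Transcriptional ITH and HLA.**  Counts → RPKM; genes filtered by
mean log2(RPKM+1) ≥ 1 and MAD ≥ threshold; average-linkage
correlation-distance clustering splits each patient's regions into two
groups; DEGs are genes with fold change ≥ 2 or ≤ 0.5 between groups;
hypergeometric gene-set enrichment with Benjamini–Hochberg adjustment;
and, pooled across all region-samples, each MHC class II gene is
regressed on the class II transactivator *CIITA* in log2 space.

## Worked example

```python
from ithpipe import simdata, variant_filter, phylo_ith, mutsig

cfg = simdata.SimConfig(seed=7)          # default study conditions
variants, expr, segs, truth = simdata.simulate_patient(cfg, "P01")

passing, report = variant_filter.apply_somatic_filters(variants)
print(report)

matrix = phylo_ith.build_matrix(passing)
res = phylo_ith.parsimony_ratchet(matrix, iterations=50, seed=7)
print(f"regions: {matrix.n_samples}  mutations: {matrix.n_mutations}")
print(f"ITH (trunk/non-trunk): {res.ith['methods']:.1f}%"
      f"   non-trunk fraction: {res.ith['nontrunk_fraction']:.1f}%")
```

prints

```
input records : 1075
passing       : 1036
rejected[strand_bias] : 12
rejected[depth] : 0
rejected[alt_reads] : 0
rejected[vaf] : 0
rejected[dbsnp_af] : 27
rejected[converge] : 0
rejected[kg_gold_indel] : 0
rejected[pop_af_0.015] : 0
rejected[region] : 0

regions: 9  mutations: 159
ITH (trunk/non-trunk): 130.4%   non-trunk fraction: 43.4%
```

The 12 strand-biased records and 27 planted germline contaminants are
removed by the filter; the surviving 159 unique mutations split into
90 trunk, 39 shared and 30 private across the nine regions, so 43.4%
of this patient's mutations are spatially heterogeneous.  Deconvolving
the trunk spectrum (80 SNVs) yields exposures
`{Signature 1: 0.77, Signature 4: 0.23}` — close to the generating
trunk mixture (0.8/0.2) — while the non-trunk spectrum needs four
signatures, mirroring the greater mutational-process complexity placed
on the branches.

The same stages are available from the shell:

```
ith simulate --out cohort/ --seed 7
ith filter --in cohort/variants.tsv --out passed.tsv --report report.json
ith phylo --in passed.tsv --patient P01 --iterations 50 --seed 7 --out phylo/
ith signatures --in passed.tsv --labels phylo/P01_labels.tsv --out sig/
ith cnv --seg cohort/segments.seg --cytobands cohort/cytobands.txt --out cnv/
ith expr --counts cohort/counts.tsv --patients cohort/patients.tsv --out expr/
```

## Input formats

- Variant TSV: one row per (mutation, region-sample) with columns
  `patient sample chrom pos ref alt depth alt_reads plus_strand_alt
  minus_strand_alt gene func exonic_func dbsnp_af converge_af kg_af
  esp_af exac_af sift polyphen` plus optional `context` (trinucleotide
  label such as `A[C>T]G`) and `kg_gold_indel` (0/1).  VCF 4.x is also
  accepted (`--dialect vcf`), with population AFs read from INFO tags.
- SEG: `ID chrom loc.start loc.end seg.mean` (1-based inclusive).
- Cytobands: UCSC cytoBand format (0-based half-open BED-like).
- Counts: genes × samples TSV with a `length` column (bases), or a
  separate two-column lengths file; GMT for gene sets.
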