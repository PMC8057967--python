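# Methods

## Setting and assumptions

`ithpipe` analyses tumors sampled in 3–9 spatially distinct regions per
patient, each region treated as a single high-purity sample (the
intended use case is patient-derived primary cell lines, where
stromal contamination is negligible; the default simulation purity is
1.0 and is configurable to probe filter behaviour at lower effective
VAF).  All stages operate per patient except the HLA association,
which pools every region-sample in the cohort.

The analysis assumes upstream processing is done: somatic calls are
annotated with read evidence and population allele frequencies, CNV
segments carry tumor-versus-normal log2 ratios, and expression is
summarised as gene-level counts.  None of those steps are recomputed
here.

## Somatic hard filter

Eight sequential criteria (strand bias < 0.9; depth ≥ 20 with alt
reads ≥ 8; VAF ≥ 0.1; dbSNP AF < 1%; not a common CONVERGE SNP; not a
1000 Genomes gold-standard INDEL; AF ≤ 0.015 in 1000 Genomes, ESP6500
and ExAC; exonic/splicing region).  Design choices:

- *Strand bias* is not a universally standardised statistic; it is
  defined here as `max(plus_alt, minus_alt) / alt_reads`, computed
  from per-strand alt counts at read time when present, otherwise
  taken from an input column.
- Boundary conventions follow the wording of the criteria exactly:
  dbSNP commonness is inclusive (≥ 0.01) while the three-database rule
  is strict (> 0.015).
- A missing population AF is treated as "not common": absence of a
  database record is not evidence of commonness.
- CONVERGE membership is consumed as an allele-frequency column with
  common meaning AF ≥ 0.01, the same 1% convention as dbSNP.
- Coverage and alt-read support are evaluated per call (per sample at
  the site), not jointly across samples.
- Rejection is attributed to the *first* failing criterion in the
  listed order, so per-criterion counts sum with passes to the input
  size.

## Phylogeny, mutation classes and the ITH score

Trunk/shared/private classification depends only on presence counts
and is therefore computed independently of any tree; the tree serves
branch-length display and the placement of changes.

Tree space is the set of unrooted topologies over the region-samples
plus a synthetic all-absent "germline" outgroup; the trunk is the edge
joining the outgroup to the rest.  Characters are binary
(absent/present) and scored with Fitch small parsimony.  Search modes:

- **Exhaustive** (`exact_tree`): all (2n−3)!! topologies are
  enumerated for n samples (practical to n = 8, i.e. 10,395
  topologies); the minimum-score topology is returned with ties broken
  by deterministic enumeration order.
- **Parsimony ratchet** (`parsimony_ratchet`): a greedy stepwise-
  addition start (random insertion order from the seed), then
  iterations of (a) doubling the weight of a random ~25% of
  characters, (b) steepest-descent hill climbing under the perturbed
  weights, (c) restoring unit weights and climbing again, (d) keeping
  the result only on strict improvement.  The climb uses the
  subtree-prune-regraft (SPR) neighbourhood rather than
  nearest-neighbour interchange: NNI's neighbourhood is too shallow on
  conflict-heavy binary matrices (in internal benchmarks pure NNI
  ratchets found the exhaustive optimum in only ~77–93% of random
  5–7-taxon matrices, SPR in ~100%), and with at most nine samples the
  SPR neighbourhood is still only a few hundred trees.  All
  randomness flows from a recorded integer seed.

Branch lengths are mutation counts.  Each character's changes are
placed by the standard minimal Fitch top-down backtrace: the root
takes the germline (absent) state whenever optimal and a child keeps
its parent's state whenever that state is in the child's Fitch set.
This placement is guaranteed score-minimal, puts every trunk mutation
on the outgroup-adjacent edge and every private mutation on a terminal
edge, and resolves homoplastic characters by retaining the ancestral
state as long as possible; characters requiring more than one change
are flagged (`homoplastic`) rather than silently resolved.  The sum of
branch lengths equals the parsimony score.

Two ITH definitions coexist in the literature this pipeline serves —
a trunk-to-non-trunk ratio and a non-trunk fraction of all mutations.
Both are always computed and reported explicitly (`methods` and
`nontrunk_fraction`); neither is silently preferred, and the ratio
definition returns NaN with a warning when there are no non-trunk
mutations.

## Mutational spectra and signatures

Substitutions are mapped into the 96 pyrimidine-centred trinucleotide
categories (purine-reference calls reverse-complemented), ordered
substitution-major.  The trunk versus non-trunk comparison uses the
chi-square test of homogeneity on the 2×6 class table; when the
non-empty table degenerates to 2×2 the Yates continuity correction is
applied, matching the behaviour of standard proportions-test
implementations.  A per-class mode (six Yates-corrected 2×2 tests) is
provided for per-class significance stars; the global 2×6 test is the
default.

Deconvolution is greedy forward selection with non-negative least
squares refits, stopping when the relative reduction in squared
reconstruction error drops below 1e-3; exposures are normalised,
exposures not exceeding the discard threshold (default 0.06, the
published default of the method this mirrors) are zeroed, and the rest
renormalised.  The threshold comparison is strict (`>`), so a
threshold of 1.0 empties the exposure vector.  Trinucleotide-abundance
rescaling is off by default; a 96-vector of per-context weights can be
supplied for exome/genome normalisation.

The bundled reference matrix is **synthetic** — generated
deterministically by `scripts/make_signature_reference.py` — because
this package ships no downloaded data.  Named columns reproduce the
qualitative structure the analysis relies on (Signature 1 C>T at
NpCpG, Signature 2 C>T/C>G at TpCpN, Signature 4 broad C>A,
Signatures 6/15 C>T with distinct context preferences, Signature 17
T>G); the remaining columns are sparse random profiles, keeping the
dictionary well conditioned for mixture recovery.  Conclusions that
depend on the *identity* of real signatures require substituting a
real reference matrix.

## CNV calls

Cytoband summaries use the overlap-length-weighted mean log2 ratio
(the band-level question is "what is the average dosage over this
band"); an `extreme` mode (largest-magnitude overlapping value,
matching the extreme-value convention of peak callers) is available.
Calls use strict inequalities against ±0.3, so a summary of exactly
0.3 is neutral.  Bands without any overlapping segment are neutral
with a missing summary value.  Coordinates are 1-based inclusive
internally; UCSC cytoband input (0-based half-open) is converted at
the reader.  Significance machinery (G-scores, q-values, peak
deconvolution) is deliberately out of scope: the heterogeneity
classification rests on the call matrix alone, and an optional band
whitelist reproduces peak-restricted displays.

## Expression

RPKM = count · 1e9 / (gene length · library size), library size being
the column sum.  Log transforms use log2(x+1) so zeros stay finite.
Variable-gene selection keeps genes with mean log2(RPKM+1) ≥ 1 and
unscaled median absolute deviation ≥ a threshold (default 1.0).
Clustering uses 1 − Pearson correlation between samples with average
linkage (the most common convention for expression heat maps;
euclidean/complete are configurable), and the bipartition is the
two-cluster cut of the dendrogram.  Fold change is computed on group
means of RPKM with ε = 0.01 added to numerator and denominator to
guard empty expression; boundaries (exactly 2 or 0.5) are included.
Enrichment is the one-sided hypergeometric tail with
Benjamini–Hochberg adjustment across sets.  The HLA panel fixes 9 MHC
class I and 16 MHC class II symbols (file-overridable); each class II
gene is fit by ordinary least squares on the regulator (default
*CIITA*) in log2(RPKM+1) space pooled over all samples, reporting
slope, intercept, Pearson r and R².  A zero-variance regulator yields
flagged NaN fits rather than an exception.

## The synthetic-data generator

What it emulates (defaults in parentheses): seven patients (7) with
3–9 regions each; ~157 somatic mutations per patient split ~97 trunk /
30 shared / 30 private plus two planted truncal driver mutations, with
~26.5% silent and 8% INDELs; Poisson depth (mean 136 reads); binomial
alt reads at clonal VAF (trunk 0.5, branch 0.4, purity 1.0); binomial
strand splits with a 1% rate of planted strand-bias outliers (≥ 0.9);
2% planted germline contaminants present in every region with elevated
population AFs; trunk contexts drawn from a Signature-1-dominated
mixture (0.8/0.2 with Signature 4) and branch contexts from a
four-component mixture, so branches carry more mutational-process
complexity than trunks; five cytoband CNV events, three fully
ubiquitous and two partial (60% and 50% of regions); 500 background +
100 DEG genes at 2.5-fold with log2 noise sd 0.1 and a balanced
two-group split; an HLA class II module driven linearly by CIITA
(slope 1.0, log2 noise sd 0.3, chosen so the pooled regulator–target
R² sits near 0.8, the level reported for this kind of design).
Mutation counts per class are exact (not Poisson-distributed) so
noiseless recovery contracts are sharp.

Shared mutations are placed on internal edges of a random bifurcating
clonal tree, so presence patterns are tree-compatible by default; an
optional homoplasy rate injects incompatible subsets to exercise the
ratchet on conflicting data.  Expression can be emitted as counts
(default; the RPKM computation is exercised, at the cost of Poisson
and rounding noise) or as exact abundances (`expr_value_kind="rpkm"`),
which the noiseless linearity contracts (R² = 1) use.

What it does **not** emulate: read-level artifacts (mapping error,
FFPE damage), subclonal VAF structure within a region, germline
haplotypes, allele-specific copy number, GC/length biases in
expression, batch effects, and a realistic karyotype (the cytoband
table is a simplified 14-band-per-chromosome genome).  Passing
recovery tests on simulated data therefore demonstrates the
correctness of the implemented procedures under their stated model,
not robustness to the full noise structure of real sequencing data.

## Problem sizes and numerical choices

The validation suite runs the parsimony comparison on 100 random
5–7-taxon matrices with 20–60 characters (50 ratchet iterations),
filter fidelity on 10,000 planted records, signature recovery on 50
mixtures of 5,000 draws (mixture weights drawn ≥ 0.15, since
components below the 0.06 discard threshold are undetectable by
construction), null calibration on 1,000 replicate pairs of 1,000
draws, and full-cohort determinism on the default seven patients; the
acceptance script scales the stochastic recovery measurements to 30
matrices / 25 mixtures / 500 replicates.  In the synthetic two-group
expression recovery the clustering step uses a MAD threshold of 0.5:
a balanced two-group gene has log2 MAD equal to half its log2 fold
change, so the planted 2.5-fold effect (gap 1.32) yields MAD ≈ 0.66,
detectable at 0.5 but categorically below the 1.0 default intended
for real data.  Reports round floats to six decimals and serialise
with sorted keys, making identical runs byte-identical.

## Known limitations

- No branch-and-bound search is implemented; exhaustive enumeration
  (exact, ≤ 8 regions) plus the ratchet cover the intended 3–9-region
  range, and beyond nine regions neither mode is tuned.
- The ratchet's optimality guarantee is empirical, not proven; ties
  between equally parsimonious topologies resolve by search order.
- The bundled signature reference is synthetic (see above).
- Driver rules treat start-loss/stop-loss variants as non-nonsense;
  they are not flagged by the truncating criterion.
- The CONVERGE and gold-INDEL criteria depend entirely on upstream
  annotation columns; no population databases ship with the package.
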