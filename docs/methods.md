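# Methods

## The analysis problem

Paired exome sequencing of a primary lung tumor and a brain metastasis
from the same patient, without a constitutional (blood) sample, poses
three linked inference problems: deciding which variant calls are
somatic at all, deciding for each somatic variant whether it predates
the metastatic seeding (truncal) or was acquired afterwards in one
compartment, and identifying chromosome-scale copy-number changes
acquired by the metastasis. This package implements one published
rule-based solution to all three, plus the descriptive layers built on
top of it (mutation spectra, trunk/branch trees, recurrence tallies),
and a synthetic data generator that makes the whole chain testable
against known ground truth.

## Somatic filtering without a matched normal

Reliability filters keep a call iff depth ≥ 10 reads, variant-supporting
reads ≥ 3, variant allele fraction ≥ 15 %, and QPHRED ≥ 20 for SNVs
(≥ 30 for indels). Without a normal sample, germline variants are then
removed by catalog lookup: any allele present in a population germline
catalog at frequency ≥ 10⁻⁵ is excluded. Both rules are deliberately
per-allele; catalog matching is exact on (chrom, pos, ref, alt).

Two numerical choices matter. VAF thresholds are evaluated as integer
cross-products (`alt_reads · q ≥ p · depth` for a threshold p/q), so a
call at exactly 15 % (e.g. 3/20) passes without float-rounding
ambiguity. The frequency bound is an exclusive upper bound for
retention: exactly 10⁻⁵ is excluded.

The residual error this scheme cannot remove — rare private germline
variants absent from catalogs — is inherent to the unmatched design and
is out of scope here; the synthetic generator catalogs every planted
germline allele, which is what lets tests demand zero germline leakage.

## Paired classification

Classification is directional, mirroring how the rules are defined:

* a variant passing QC in the **primary** is *shared* iff the metastasis
  shows ≥ 2 variant reads forming ≥ 5 % of its coverage at the site,
  else *primary-specific*;
* a variant passing QC **only in the metastasis** is
  *metastasis-specific* iff it shows ≥ 3 reads at ≥ 15 % there while the
  primary shows ≤ 1 read at < 5 % (strict);
* a metastasis-only variant failing that evidence rule is *unresolved*:
  it is reported for audit but excluded from trunk/branch counts, since
  the rule set does not define its compartment.

Degenerate coverage is handled conservatively: zero metastasis depth
makes sharing unsatisfiable (primary-specific); zero primary depth with
zero variant reads counts as a 0 % primary fraction. Applying the rules
requires primary read depth at sites called only in the metastasis; the
variant-table dialect therefore carries per-site depth rows for both
compartments (the generator always emits them; real-data users must
supply pileup depth).

## Copy-number segmentation

Per-bin log₂(met/primary) ratios are computed after library-size
normalization (each sample's bin depths divided by its total), with
bins masked when primary depth < 10 reads — the same evidence floor as
the variant filters. Log base 2 is the community convention for
coverage ratios.

Segmentation is circular binary segmentation: over the circularized
value vector, find the arc maximizing |mean(arc) − mean(complement)| /
pooled SE, accept the split if its permutation p-value < α (default
0.01, 1000 permutations, minimum segment width 3 bins), recurse on the
pieces. Implementation notes:

* The arc search is exact (all O(n²) arcs, vectorized); ties take the
  lexicographically first (i, j). A zero pooled SE with a nonzero mean
  difference (a noise-free step) scores +∞ and wins, as it should.
* The permutation loop stops early once the exceedance count already
  forces p ≥ α; this cannot change any accept/reject decision.
* After recursion, each internal boundary is re-optimized locally
  (± 5 bins, residual-sum-of-squares criterion, both neighbors kept at
  minimum width). The arc statistic locates both edges of a split
  jointly, so one edge can sit a few bins off its optimum when noise is
  appreciable; the sweep corrects that. Merging of adjacent
  like-valued segments ("undo splits") is deliberately not performed.
* Everything is deterministic given the seed.

**Zero level.** The copy-neutral baseline is the most frequent smoothed
segment value. For continuous values this needs an estimator: we use
the mode of a Gaussian kernel density over segment values, weighted by
segment bin counts, bandwidth 0.05 log₂ units (well below the 0.15
call offset), evaluated at the segment values themselves. A fixed-grid
histogram was considered and rejected: when the neutral genome is split
across two segments whose means straddle a histogram edge, its mass
halves and a large altered segment can capture the mode, inverting the
baseline; the kernel mode pools nearby neutral segments regardless of
edge placement and is exactly translation-equivariant. Near-ties
resolve to the candidate nearest 0.

**State calling.** Relative to zero: > +0.15 gain, > +2 amplification,
< −0.15 deletion, < −2 homozygous deletion; "above"/"below" are strict,
and the extreme labels subsume the mild ones. Calling is therefore
invariant under adding a constant to all bins. Cross-patient recurrent
regions are maximal bin runs where ≥ k patients share a gain-like
(or deletion-like) state; cytoband naming is out of scope.

## Mutational spectra and clustering

Each somatic SNV maps to one of 96 categories: 6 substitution types on
the pyrimidine strand (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking-base
contexts. Purine-reference records are reverse-complemented (swapping
and complementing the flanks), making the spectrum strand-collapse
invariant. Canonical ordering is substitution block, then 5′ base, then
3′ base, alphabetical.

Samples are compared on proportion-normalized spectra: PCA (mean-
centered, full SVD, 2 components by default) and agglomerative
clustering on pairwise cosine dissimilarities with Ward's linkage
update. Ward's method formally assumes squared Euclidean distances;
applying it to cosine dissimilarities is a deliberate reproduction of
the published procedure, not an endorsement — the caveat is that merge
heights lose their variance interpretation, though for well-separated
profiles the 2-group cut is unaffected. Dendrograms are serialized to
Newick with branch lengths derived from merge heights. All-zero
spectra are excluded with a warning. Transcription-strand bias and
COSMIC signature decomposition are out of scope.

## Evolution reports

A two-sample pair supports exactly one tree shape,
`((primary:a, met:b)trunk:s);` with branch lengths equal to mutation
counts; trunk = shared, branches = compartment-private. Recurrence
tallies count **distinct patients** with ≥ 1 metastasis-private
non-synonymous mutation per gene (synonymous hits can be included by
flag); cancer-gene annotation flags variants in a user-supplied gene
list and reports flagged non-synonymous SNVs and indels; domain overlap
joins variants with protein positions to 1-based inclusive domain
spans. Protein positions are an input column from upstream annotation,
never computed here.

## The synthetic cohort generator

The generator emulates the paired study design, not raw sequencing:

* **Cohort shape** — 7 patients by default, two samples each, median
  depth 135X. Per-site depth is Poisson(median_depth) floored at 1;
  variant reads are Binomial(depth, VAF); QPHRED is Normal(mean 60,
  sd 5) truncated at 0 and rounded.
* **Variant origins** — per patient: 200 germline variants (VAF 0.5 in
  both compartments, catalogued at frequency ≥ 10⁻⁵), 119 truncal and
  19 primary-private plus 52 metastasis-private somatic variants
  (single configurable VAF per class, default 0.4). The somatic counts
  reproduce a primary-tumor median of ~138 SNVs and a metastasis-
  acquired median of ~52; the ~20 % indel fraction matches the reported
  SNV:indel ratios. Both samples carry a depth row for every patient
  site, so paired classification always has cross-compartment evidence.
* **What is not modeled** — sequencing error (no variant reads at
  wild-type sites), tumor purity/subclonality (one VAF per origin
  class), mappability, GC bias, and a real reference genome
  (chromosomes are abstract bin grids; trinucleotide contexts are drawn
  uniformly and carried as columns). Passing tests therefore
  demonstrate rule correctness and recovery under clean evidence, not
  robustness to noisy real-world calls — with default depths and VAFs
  the classification margins are many binomial standard deviations
  wide, which is what makes exact-recovery assertions meaningful.
* **Planted structure** — copy-number segments (default +0.6 on chr1,
  −0.8 on chr2, metastasis only; bin depths are median·2^(lr+ε) with
  ε ~ N(0, 0.1) log₂ noise), a recurrent metastasis-private missense
  gene planted in 3 patients, substitution types drawn from a
  C>A-dominant profile emulating tobacco-associated spectra, a
  20-gene cancer list containing the planted gene, and a small domain
  table. Everything is deterministic under a fixed seed.

## Verification strategy and problem sizes

Unit and property tests cover each rule's boundaries (exactly 5 %,
15 %, 1/2/3 reads, QPHRED 20/30, frequency 10⁻⁵), monotonicity /
idempotence / partition properties of the QC pipeline, strand-collapse
invariance, and Newick round-trips through an external parser. The
segmentation arc search is validated against an independently coded
exhaustive search on ≤ 50-bin instances; planted-segment recovery is
measured over 100 simulations (120 bins, 40-bin segments at |log₂| 0.6,
noise sd 0.1, 200 permutations) requiring both region boundaries within
± 2 bins with the correct state; spectrum separation uses 20 cohorts of
2 × 4 samples at 200 SNVs each; the end-to-end check runs 7 patients at
reduced per-patient counts (50/10/10 somatic, 40 germline, 60-bin
chromosomes). These sizes keep the full suite under a minute of compute
while leaving the statistical margins of each check far from its
threshold.

## Known limitations

* The unresolved class and the directional sharing rule mean a variant
  present in both compartments but QC-passing only in the metastasis is
  never called shared; this mirrors the rule set's asymmetry.
* The kernel-mode zero level assumes the neutral state occupies a
  plurality of bins; a genome mostly altered in one direction would
  mis-anchor, as any mode-based baseline would.
* CBS power at the default α = 0.01 and 3-bin minimum width is limited
  for short or shallow segments; segments shorter than 3 bins are
  undetectable by construction.
* Ward-on-cosine clustering is reproduced as published; for spectra
  with subtle differences a Euclidean embedding or spherical k-means
  would be better founded.
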